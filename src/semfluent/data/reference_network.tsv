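alpaca	chicken
alpaca	coyote
alpaca	koala
alpaca	raccoon
ant	coyote
ant	duck
ant	monkey
ant	rabbit
ant	sheep
bat	crow
bat	opossum
bat	raccoon
bat	rhinoceros
bear	cheetah
bear	coyote
bear	deer
bear	gorilla
bear	lion
bear	rhinoceros
camel	chicken
camel	elephant
camel	hawk
camel	otter
camel	owl
camel	penguin
camel	rabbit
cat	chimpanzee
cat	deer
cat	koala
cat	rabbit
cheetah	hawk
cheetah	kangaroo
cheetah	lizard
cheetah	monkey
cheetah	moose
cheetah	mouse
cheetah	robin
cheetah	salamander
chicken	crab
chicken	deer
chicken	horse
chicken	moose
chicken	mouse
chimpanzee	crow
chimpanzee	giraffe
chimpanzee	leopard
chimpanzee	llama
chimpanzee	octopus
chimpanzee	rabbit
chimpanzee	rhinoceros
chimpanzee	seal
chimpanzee	shark
chimpanzee	sheep
chipmunk	dolphin
chipmunk	lion
chipmunk	sheep
cow	crab
cow	crow
cow	elk
cow	giraffe
cow	lizard
cow	otter
cow	penguin
coyote	dog
coyote	frog
coyote	goat
coyote	horse
coyote	jaguar
coyote	lion
coyote	mouse
coyote	rat
coyote	sheep
crab	elephant
crab	giraffe
crab	octopus
crab	rabbit
crab	raccoon
crab	rat
crab	rhinoceros
crab	salamander
crab	salmon
crab	snake
crow	dolphin
crow	elephant
crow	llama
crow	lobster
crow	monkey
crow	owl
crow	penguin
crow	robin
crow	salamander
crow	seal
crow	sheep
deer	elk
deer	frog
deer	gorilla
deer	koala
deer	leopard
deer	monkey
deer	pig
deer	rabbit
deer	raccoon
dog	eagle
dog	frog
dog	horse
dog	mouse
dog	octopus
dog	robin
dog	snake
dolphin	goat
dolphin	kangaroo
dolphin	leopard
dolphin	lion
dolphin	lobster
dolphin	monkey
dolphin	opossum
dolphin	seal
duck	eagle
duck	elephant
duck	hawk
duck	lobster
duck	penguin
duck	robin
duck	shark
eagle	elephant
eagle	elk
eagle	pig
eagle	rabbit
elephant	goose
elephant	skunk
elk	goat
elk	gorilla
elk	hawk
elk	jaguar
elk	koala
elk	lion
elk	moose
elk	owl
elk	raccoon
fox	frog
fox	hawk
fox	leopard
fox	lizard
fox	otter
fox	salmon
fox	seal
fox	snake
frog	hippopotamus
frog	kangaroo
frog	rabbit
frog	raccoon
giraffe	hawk
giraffe	rhinoceros
goat	leopard
goat	lion
goat	moose
goat	octopus
goose	lobster
gorilla	koala
gorilla	leopard
gorilla	llama
gorilla	mouse
gorilla	opossum
gorilla	panda
gorilla	rabbit
gorilla	rat
gorilla	seal
hawk	opossum
hawk	rhinoceros
hawk	shark
hawk	snake
hippopotamus	llama
hippopotamus	panda
hippopotamus	salamander
hippopotamus	seal
horse	lizard
horse	llama
horse	monkey
horse	mouse
horse	octopus
horse	otter
horse	owl
horse	salamander
horse	seal
horse	snake
jaguar	leopard
jaguar	panda
jaguar	skunk
kangaroo	lizard
kangaroo	lobster
kangaroo	monkey
kangaroo	moose
koala	panda
koala	salmon
leopard	salmon
lion	owl
lion	panda
lizard	rhinoceros
lizard	skunk
llama	lobster
llama	rhinoceros
llama	seal
lobster	penguin
lobster	sheep
monkey	mouse
monkey	octopus
monkey	owl
monkey	rhinoceros
moose	otter
moose	penguin
moose	salmon
moose	snake
mouse	penguin
mouse	raccoon
mouse	salamander
mouse	skunk
octopus	robin
octopus	salamander
octopus	seal
opossum	penguin
otter	snake
owl	panda
owl	raccoon
owl	sheep
panda	rabbit
panda	rhinoceros
panda	salamander
penguin	pig
penguin	rabbit
penguin	rhinoceros
penguin	shark
pig	robin
pig	snake
raccoon	rhinoceros
raccoon	seal
rat	salmon
rhinoceros	skunk
robin	sheep
seal	sheep
shark	sheep
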
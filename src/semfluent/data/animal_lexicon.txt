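# Toy animal lexicon for the category-fluency task (one canonical item per line).
# User-replaceable: any plain-text list of canonical (lower-case, trimmed) items works.
dog
cat
horse
cow
pig
sheep
goat
chicken
duck
goose
turkey
rabbit
mouse
rat
squirrel
chipmunk
deer
moose
elk
bear
wolf
fox
coyote
raccoon
skunk
opossum
bat
lion
tiger
leopard
cheetah
jaguar
elephant
rhinoceros
hippopotamus
giraffe
zebra
gorilla
chimpanzee
monkey
kangaroo
koala
panda
camel
llama
alpaca
whale
dolphin
seal
walrus
otter
penguin
eagle
hawk
owl
crow
robin
sparrow
snake
lizard
turtle
frog
salamander
shark
salmon
trout
octopus
crab
lobster
ant
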
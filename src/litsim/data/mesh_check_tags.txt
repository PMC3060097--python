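# MeSH check tags (Class 3): demographic/species descriptors attached to most
# records; used as a fallback when records carry no class metadata.
Humans
Animals
Male
Female
Adult
Middle Aged
Aged
Aged, 80 and over
Adolescent
Young Adult
Child
Child, Preschool
Infant
Infant, Newborn
Pregnancy
Mice
Rats
Cattle
Cats
Dogs
Rabbits
Swine
Sheep
Horses
Guinea Pigs
Cricetinae
Chick Embryo
Comparative Study
Case Reports
In Vitro
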
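species,common_name,taxon_order,group,mass_kg,island_proportion,n_total,biomass_printed
Cephalophus ogilbyi ogilbyi,Ogilby's Duiker,Artiodactyla,ungulate,19.50,1.00,9381,182929.50
Philantomba monticola,Blue Duiker,Artiodactyla,ungulate,4.90,1.00,49318,241658.20
Potamochoerus porcus,Red River Hog,Artiodactyla,ungulate,80.00,0.00,266,21280.00
Ceratogymna atrata,Black-casqued Hornbill,Aves,avian,1.50,1.00,1473,2209.50
Corythaeola cristata,Great Blue Turaco,Aves,avian,1.20,1.00,2259,2710.80
Gypohierax angolensis,Palm-nut Vulture,Aves,avian,2.00,0.99,391,782.00
Nandinia binotata,African Palm Civet,Carnivora,other,2.95,0.00,1241,3660.95
Poiana richardsonii,African Linsang,Carnivora,other,0.60,0.11,588,352.80
Dendrohyrax dorsalis,Western Tree Hyrax,Hyracoidea,other,3.00,1.00,1553,4659.00
Manis tricuspis,Tree Pangolin,Pholidota,other,1.50,0.50,6302,9453.00
Smutsia gigantea,Giant Ground Pangolin,Pholidota,other,32.50,0.00,118,3835.00
Allochrocebus preussi insularis,Bioko Preuss's Monkey,Primates,primate,4.50,1.00,2142,9639.00
Cercopithecus erythrotis erythrotis,Bioko Red-eared Monkey,Primates,primate,3.40,1.00,17997,61189.80
Cercopithecus nictitans martini,Stampfli's Putty-Nosed Monkey,Primates,primate,4.60,0.98,336,1545.60
Cercopithecus pogonias pogonias,Golden-bellied Crowned Monkey,Primates,primate,3.25,1.00,2720,8840.00
Colobus satanas satanas,Bioko Black Colobus,Primates,primate,9.25,1.00,5122,47378.50
Mandrillus leucophaeus poensis,Bioko Drill,Primates,primate,14.25,1.00,5004,71307.00
Procolobus pennantii,Pennant's Red Colobus,Primates,primate,10.50,1.00,1754,18417.00
Sciurocheirus alleni alleni,Bioko Allen's Galago,Primates,primate,0.26,1.00,160,41.60
Kinyxis erosa,Serrated Hinge-back Tortoise,Reptilia,reptile,1.00,0.00,3323,3323.00
Osteolaemus tetraspis,Dwarf Crocodile,Reptilia,reptile,7.50,0.00,1913,14347.50
Python sebae,African Rock Python,Reptilia,reptile,13.83,1.00,1001,13841.41
Varanus niloticus,Nile Monitor,Reptilia,reptile,6.50,0.45,1618,10517.00
Atherurus africanus,African Brush-tailed Porcupine,Rodentia,rodent,2.83,0.91,24302,68798.96
Cricetomys emini,Emin's Pouched Rat,Rodentia,rodent,1.14,1.00,44624,50871.36
Myosciurus pumilio,African Pygmy Squirrel,Rodentia,rodent,0.02,1.00,105,2.10
Protoxerus stangeri,African Giant Squirrel,Rodentia,rodent,0.77,1.00,9967,7674.59
Thryonomys swinderianus,Greater Cane Rat,Rodentia,rodent,6.65,0.00,1914,12728.10
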
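species,common_name,accession,edp_days,edpr_printed,egg_mass_g,clutch_size,foraging,activity,nest
Alca torda,Razorbill,AJ242683,35,5.44,95.70,1,0,1,0
Alle alle,Dovekie,AJ242684,29,3.12,31.30,1,1,1,0
Uria aalge,Common murre,AJ242686,33,2.92,110.80,1,0,1,1
Uria lomvia,Thick-billed murre,AJ242687,33,3.01,107.80,1,1,1,1
Synthliboramphus wumizusume,Japanese murrelet,U37306,31,4.63,36.60,2,1,0,0
Synthliboramphus antiquus,Ancient murrelet,U37303,34,6.99,44.80,2,1,0,0
Synthliboramphus hypoleucus,Xantus' murrelet,U37305,34,7.58,37.20,2,1,0,0
Cepphus carbo,Spectacled guillemot,U37292,27,-1.24,65.10,2,0,1,0
Cepphus columba,Pigeon guillemot,U37293,28,0.20,57.00,2,0,1,0
Cepphus grylle,Black guillemot,AJ242688,29,1.77,47.90,2,0,1,0
Brachyramphus marmoratus,Marbled murrelet,U63055,29,2.47,38.50,1,0,0,1
Ptychoramphus aleuticus,Cassin's auklet,U37302,39,13.33,29.20,1,1,0,0
Aethia pusilla,Least auklet,U37104,30,5.66,18.70,1,1,1,0
Aethia cristatella,Crested auklet,U37087,34,7.66,36.30,1,1,1,0
Cyclorrhynchus psittacula,Parakeet auklet,U37296,35,8.55,37.60,1,1,1,0
Cerorhinca monocerata,Rhinoceros auklet,U37295,45,16.10,79.20,1,1,0,0
Fratercula corniculata,Horned puffin,U37299,40,11.24,75.90,1,1,1,0
Fratercula arctica,Atlantic puffin,U37297,41,12.52,70.00,1,1,1,0
Fratercula cirrhata,Tufted puffin,U37298,44,14.65,90.00,1,1,1,0
Aptenodytes forsteri,Emperor penguin,DQ137225,64,28.32,465.00,1,1,1,1
Aptenodytes patagonicus,King penguin,AY139623,54,20.00,310.00,1,1,1,1
Eudyptula minor,Little blue penguin,NC_004538,34.7,7.14,53.00,2,0,1,0
Eudyptes chrysocome,Rockhopper penguin,AF076051,34,3.68,118.40,2,1,1,1
Eudyptes chrysolophus,Macaroni penguin,AF076052,35.45,4.28,149.46,2,1,1,1
Eudyptes pachyrhynchus,Fiordland penguin,DQ137210,33.5,3.18,118.40,2,0,1,1
Eudyptes sclateri,Erect-crested penguin,DQ137209,35,3.80,150.70,2,-,1,1
Pygoscelis adeliae,Adelie penguin,GQ925801,33,2.63,120.10,2,0,1,1
Pygoscelis antarctica,Chinstrap penguin,AF076089,34,3.81,114.10,2,0,1,1
Pygoscelis papua,Gentoo penguin,AF076090,35,4.42,127.08,2,0,1,1
Spheniscus demersus,Black-footed penguin,DQ137217,38,8.05,106.80,2,0,1,0
Spheniscus humboldti,Peruvian penguin,AY567916,40.7,10.18,125.00,2,0,1,0
Spheniscus magellanicus,Magellanic penguin,DQ137218,41.2,10.65,126.25,2,0,1,0
Megadyptes antipodes,Yellow-eyed penguin,DQ137224,43.5,12.64,137.20,2,-,1,1
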
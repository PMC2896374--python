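((((('Uria aalge','Uria lomvia'),('Alca torda','Alle alle')),('Synthliboramphus wumizusume',('Synthliboramphus antiquus','Synthliboramphus hypoleucus'))),((('Cepphus carbo',('Cepphus columba','Cepphus grylle')),'Brachyramphus marmoratus'),(('Ptychoramphus aleuticus',('Aethia pusilla',('Aethia cristatella','Cyclorrhynchus psittacula'))),('Cerorhinca monocerata',('Fratercula corniculata',('Fratercula arctica','Fratercula cirrhata')))))),(('Aptenodytes forsteri','Aptenodytes patagonicus'),(('Pygoscelis adeliae',('Pygoscelis antarctica','Pygoscelis papua')),(('Megadyptes antipodes',('Eudyptes chrysocome',('Eudyptes chrysolophus',('Eudyptes pachyrhynchus','Eudyptes sclateri')))),('Eudyptula minor',('Spheniscus demersus',('Spheniscus humboldti','Spheniscus magellanicus')))))));
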
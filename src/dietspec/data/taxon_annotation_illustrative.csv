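taxon,order,habitat,is_salmonid,salmonid_species
Clupea pallasii,Clupeiformes,pelagic,0,
Engraulis mordax,Clupeiformes,pelagic,0,
Oncorhynchus tshawytscha,Salmoniformes,pelagic,1,Chinook
Oncorhynchus keta,Salmoniformes,pelagic,1,Chum
Oncorhynchus kisutch,Salmoniformes,pelagic,1,Coho
Oncorhynchus gorbuscha,Salmoniformes,pelagic,1,Pink
Oncorhynchus nerka,Salmoniformes,pelagic,1,Sockeye
Gadus macrocephalus,Gadiformes,demersal,0,
Merluccius productus,Gadiformes,demersal,0,
Microgadus proximus,Gadiformes,demersal,0,
Theragra chalcogramma,Gadiformes,demersal,0,
Parophrys vetulus,Pleuronectiformes,benthic,0,
Platichthys stellatus,Pleuronectiformes,benthic,0,
Hippoglossoides elassodon,Pleuronectiformes,benthic,0,
Sebastes caurinus,Scorpaeniformes,benthic,0,
Leptocottus armatus,Scorpaeniformes,benthic,0,
Hemilepidotus hemilepidotus,Scorpaeniformes,benthic,0,
Embiotoca lateralis,Perciformes,demersal,0,
Rhacochilus vacca,Perciformes,demersal,0,
Ammodytes hexapterus,Perciformes,pelagic,0,
Porichthys notatus,Batrachoidiformes,benthic,0,
Hydrolagus colliei,Chimaeriformes,demersal,0,
Raja rhina,Rajiformes,benthic,0,
Entosphenus tridentatus,Petromyzontiformes,pelagic,0,
Thaleichthys pacificus,Osmeriformes,pelagic,0,
Hypomesus pretiosus,Osmeriformes,pelagic,0,
Gasterosteus aculeatus,Gasterosteiformes,pelagic,0,
Doryteuthis opalescens,Cephalopoda,pelagic,0,
Octopus rubescens,Cephalopoda,benthic,0,
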
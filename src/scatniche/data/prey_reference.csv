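taxon,family,ftl,max_total_length_mm,ftl_source
Strongylura hubbsi,Belonidae,3.9,460,FishBase-style estimate
Strongylura marina,Belonidae,4.1,1110,FishBase-style estimate
Caranx latus,Carangidae,4.1,1010,FishBase-style estimate
Centropomus ensiferus,Centropomidae,4.0,680,FishBase-style estimate
Astianax fasciatus,Characidae,2.8,170,FishBase-style estimate
Chuco intermedius,Cichlidae,2.5,287,FishBase-style estimate
Cincelichthys bocourti,Cichlidae,2.1,335,FishBase-style estimate
Cincelichthys pearsei,Cichlidae,2.2,377,FishBase-style estimate
Cribroheros robertsoni,Cichlidae,3.1,225,FishBase-style estimate
Kihmchithys ufermammi,Cichlidae,2.5,350,FishBase-style estimate
Maskaheros argenteus,Cichlidae,,337,no FTL available
Mayaheros urophtalmus,Cichlidae,3.4,394,FishBase-style estimate
Oreochromis aureus,Cichlidae,2.1,457,FishBase-style estimate
Parachromis friedrichsthalii,Cichlidae,3.8,250,FishBase-style estimate
Petenia splendida,Cichlidae,4.0,500,FishBase-style estimate
Rheoheros lentiginosus,Cichlidae,3.0,170,FishBase-style estimate
Rocio octofasciata,Cichlidae,3.3,250,FishBase-style estimate
Thorichthys affinis,Cichlidae,3.2,110,FishBase-style estimate
Thorichthys aureus,Cichlidae,3.2,130,FishBase-style estimate
Thorichthys meeki,Cichlidae,3.1,170,FishBase-style estimate
Thorichthys pasionis,Cichlidae,3.1,173,FishBase-style estimate
Trichromis salvini,Cichlidae,3.9,220,FishBase-style estimate
Vieja bifasciata,Cichlidae,2.4,300,FishBase-style estimate
Vieja melanurus,Cichlidae,2.2,350,FishBase-style estimate
Ctenopharyngodon idella,Cyprinidae,2.0,1500,FishBase-style estimate
Dormitator maculatus,Eleotridae,2.2,700,FishBase-style estimate
Eugerres mexicanus,Gerreidae,3.2,350,FishBase-style estimate
Hyporhamphus mexicanus,Hemiramphidae,2.6,200,FishBase-style estimate
Aractosteus tropicus,Lepisosteidae,4.2,1250,FishBase-style estimate
Pterygoplichthys spp,Loricariidae,2.0,500,FishBase-style estimate
Megalops atlanticus,Megalopidae,4.3,2500,FishBase-style estimate
Mugil cephalus,Mugilidae,2.5,1000,FishBase-style estimate
Belonesox belizanus,Poeciliidae,4.3,200,FishBase-style estimate
Poecilia mexicana,Poeciliidae,2.2,110,FishBase-style estimate
Poecilia petenensis,Poeciliidae,2.2,120,FishBase-style estimate
Catfish,Ariidae/Heptapteridae/Ictaluridae,3.5,600,group-level FishBase-style estimate
Potamocarcinus sp,Pseudothelphusidae,2.6,160,mean FTL reported for similar freshwater crabs
Macrobrachium sp,Palaemonidae,,250,no FTL available
Unknown Insects,,,,no FTL available
Unknown Reptile,,,,no FTL available
Unknown Mammal,,,,no FTL available
Unknown,,,,no FTL available
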
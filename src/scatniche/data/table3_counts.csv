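river,year,n_scats,taxon,count
Mopan,2016,40,Strongylura marina,1
Mopan,2016,40,Caranx latus,1
Mopan,2016,40,Centropomus ensiferus,1
Mopan,2016,40,Chuco intermedius,6
Mopan,2016,40,Cincelichthys bocourti,1
Mopan,2016,40,Cribroheros robertsoni,1
Mopan,2016,40,Mayaheros urophtalmus,2
Mopan,2016,40,Oreochromis aureus,8
Mopan,2016,40,Parachromis friedrichsthalii,2
Mopan,2016,40,Thorichthys aureus,6
Mopan,2016,40,Thorichthys meeki,5
Mopan,2016,40,Dormitator maculatus,1
Mopan,2016,40,Poecilia mexicana,1
Mopan,2016,40,Catfish,8
Mopan,2016,40,Potamocarcinus sp,32
Mopan,2016,40,Unknown Insects,3
Mopan,2016,40,Unknown Reptile,3
Mopan,2016,40,Unknown Mammal,1
Mopan,2016,40,Unknown,8
Pasion,2010,52,Cribroheros robertsoni,13
Pasion,2010,52,Maskaheros argenteus,1
Pasion,2010,52,Mayaheros urophtalmus,5
Pasion,2010,52,Oreochromis aureus,5
Pasion,2010,52,Parachromis friedrichsthalii,9
Pasion,2010,52,Petenia splendida,1
Pasion,2010,52,Rheoheros lentiginosus,1
Pasion,2010,52,Rocio octofasciata,2
Pasion,2010,52,Thorichthys affinis,2
Pasion,2010,52,Thorichthys meeki,11
Pasion,2010,52,Thorichthys pasionis,10
Pasion,2010,52,Vieja bifasciata,3
Pasion,2010,52,Vieja melanurus,3
Pasion,2010,52,Ctenopharyngodon idella,7
Pasion,2010,52,Mugil cephalus,1
Pasion,2010,52,Pterygoplichthys spp,14
Pasion,2010,52,Belonesox belizanus,5
Pasion,2010,52,Poecilia mexicana,3
Pasion,2010,52,Poecilia petenensis,11
Pasion,2010,52,Catfish,3
Pasion,2010,52,Potamocarcinus sp,30
Pasion,2010,52,Unknown,2
Pasion,2015,40,Cincelichthys bocourti,1
Pasion,2015,40,Cribroheros robertsoni,4
Pasion,2015,40,Mayaheros urophtalmus,5
Pasion,2015,40,Oreochromis aureus,6
Pasion,2015,40,Parachromis friedrichsthalii,5
Pasion,2015,40,Rheoheros lentiginosus,1
Pasion,2015,40,Rocio octofasciata,1
Pasion,2015,40,Thorichthys meeki,2
Pasion,2015,40,Thorichthys pasionis,1
Pasion,2015,40,Vieja bifasciata,6
Pasion,2015,40,Vieja melanurus,1
Pasion,2015,40,Pterygoplichthys spp,36
Pasion,2015,40,Poecilia mexicana,1
Pasion,2015,40,Poecilia petenensis,1
Pasion,2015,40,Catfish,1
Pasion,2015,40,Unknown Reptile,1
San Pedro,2009,36,Strongylura hubbsi,3
San Pedro,2009,36,Astianax fasciatus,9
San Pedro,2009,36,Cribroheros robertsoni,22
San Pedro,2009,36,Kihmchithys ufermammi,3
San Pedro,2009,36,Mayaheros urophtalmus,5
San Pedro,2009,36,Oreochromis aureus,4
San Pedro,2009,36,Parachromis friedrichsthalii,1
San Pedro,2009,36,Thorichthys meeki,10
San Pedro,2009,36,Thorichthys pasionis,10
San Pedro,2009,36,Vieja bifasciata,1
San Pedro,2009,36,Hyporhamphus mexicanus,9
San Pedro,2009,36,Aractosteus tropicus,1
San Pedro,2009,36,Pterygoplichthys spp,23
San Pedro,2009,36,Belonesox belizanus,1
San Pedro,2009,36,Poecilia mexicana,17
San Pedro,2009,36,Poecilia petenensis,17
San Pedro,2009,36,Catfish,3
San Pedro,2015,117,Astianax fasciatus,1
San Pedro,2015,117,Chuco intermedius,1
San Pedro,2015,117,Cincelichthys bocourti,1
San Pedro,2015,117,Cincelichthys pearsei,1
San Pedro,2015,117,Cribroheros robertsoni,12
San Pedro,2015,117,Kihmchithys ufermammi,1
San Pedro,2015,117,Mayaheros urophtalmus,17
San Pedro,2015,117,Oreochromis aureus,21
San Pedro,2015,117,Parachromis friedrichsthalii,4
San Pedro,2015,117,Petenia splendida,3
San Pedro,2015,117,Rocio octofasciata,3
San Pedro,2015,117,Thorichthys affinis,1
San Pedro,2015,117,Thorichthys meeki,25
San Pedro,2015,117,Thorichthys pasionis,8
San Pedro,2015,117,Trichromis salvini,2
San Pedro,2015,117,Vieja bifasciata,21
San Pedro,2015,117,Vieja melanurus,8
San Pedro,2015,117,Ctenopharyngodon idella,5
San Pedro,2015,117,Eugerres mexicanus,4
San Pedro,2015,117,Hyporhamphus mexicanus,2
San Pedro,2015,117,Pterygoplichthys spp,75
San Pedro,2015,117,Megalops atlanticus,1
San Pedro,2015,117,Belonesox belizanus,12
San Pedro,2015,117,Poecilia mexicana,24
San Pedro,2015,117,Poecilia petenensis,26
San Pedro,2015,117,Catfish,4
San Pedro,2015,117,Potamocarcinus sp,3
San Pedro,2015,117,Macrobrachium sp,1
San Pedro,2015,117,Unknown,2
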
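locality,age,tree_taxon,tree_group,resin_class,mass_min_g,mass_max_g,total_mass_g,mass_approximate,total_inclusions,citation
"Mananjary region (between Nosy Varika and Ambahy), Madagascar","Resin collected in 2013","Hymenaea verrucosa (Caesalpiniaceae)",hymenaea,defaunation,,,800.5,False,1743,"Solorzano-Kraemer et al. 2015"
"Sacaramy (close to Antsiranana, Diego Suarez), Madagascar","Resin collected in 2015","Hymenaea verrucosa (Caesalpiniaceae)",hymenaea,defaunation,,,1500,False,2141,"Own data"
"Col de Yate South Province (Gramseat South), New Caledonia","Resin collected in 2016","Agathis ovata (Araucariaceae)",agathis,defaunation,,,1627.1,False,40,"Own data"
"Bon Secours (close to Riviere Bleue Provincial Park, South Province, Gramseat South), New Caledonia","Resin collected in 2016","Agathis lanceolata (Araucariaceae)",agathis,defaunation,,,991.6,False,8,"Own data"
"Copal/Defaunation resin from Cotui, Dominican Republic","Unknown","Hymenaea courbaril (Caesalpiniaceae)",hymenaea,copal,,,1875.2,False,319,"Own data"
"Amber from Totolapa, Chiapas, Mexico","Early Miocene","Hymenaea mexicana (Caesalpiniaceae)",hymenaea,amber,,,2000,False,107,"Solorzano-Kraemer et al. 2010"
"Amber from El Valle 7 Canadas, Dominican Republic","Early Miocene","Hymenaea protera (Caesalpiniaceae)",hymenaea,amber,,,1678.8,False,270,"Own data"
"Amber from San Rafael, Dominican Republic","Early Miocene","Hymenaea protera (Caesalpiniaceae)",hymenaea,amber,,,523.5,False,140,"Own data"
"Amber from Southland region of the South Island, and Otago, New Zealand","Late Oligocene and early Miocene","Agathis sp. (Araucariaceae)",agathis,amber,1000,1500,1250,True,78,"Schmidt et al. 2018; A. Schmidt pers. comm. 2023"
"Amber from Anglesea Coal Measures (ACM), Australia","Early Eocene","Agathis sp.",agathis,amber,,,2000,True,47,"Stilwell et al. 2020; own data 2025"
"Amber from Macquarie Harbour Formation (MHF), Australia","Early Eocene","Agathis sp.",agathis,amber,,,1500,True,2,"Stilwell et al. 2020; own data 2025"
"Amber from Fourtou, France","Middle Cenomanian","Agathoxylon sp. (Araucariaceae) or Cheirolepidiaceae",agathis_like,amber,,,2000,True,40,"Girard et al.; own data 2025"
"Amber from Fouras/Bois Vert, France","Early Cenomanian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,,,3000,True,113,"Neraudeau et al.; Perrichot et al.; own data 2025"
"Amber from Ile d'Aix, France","Early Cenomanian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,,,500,True,6,"Neraudeau et al.; own data 2025"
"Amber from La Buzinie, France","Early Cenomanian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,,,6000,True,149,"Perrichot et al.; own data 2025"
"Amber from Salignac, France","Early Cenomanian","Araucariaceae",agathis_like,amber,,,400,True,27,"Perrichot et al.; own data 2025"
"Amber from Archingeay-Les Nouillers, France","Late Albian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,35000,40000,37500,True,1330,"Perrichot et al.; own data 2025"
"Amber from Les Renardieres, France","Late Albian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,,,300,False,4,"Perrichot et al.; own data 2025"
"Amber from Cadeuil, France","Late Albian","Agathoxylon gardoniense (Araucariaceae) and Cheirolepidiaceae",agathis_like,amber,,,8000,True,98,"Neraudeau et al.; own data 2025"
"Amber from Penacerrada, Alava, Spain","Late Albian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,139500,False,3346,"Own data"
"Amber from San Just, Teruel, Spain","Late Albian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,12900,False,387,"Own data"
"Amber from La Hoya, Castellon, Spain","Early Cenomanian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,5500,False,11,"Own data"
"Amber from El Soplao, Cantabria, Spain","Middle Albian (Early Cretaceous)","Frenelopsis sp. (Cheirolepidiaceae) and other possible Cupressaceae",cheirolepidiaceae,amber,,,19937,False,1600,"Own data"
"Amber from Arroyo de la Pascueta, Teruel, Spain","Late Albian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,7000,False,14,"Own data"
"Amber from La Rodada, La Manjoya, Spain","Late Albian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,500,False,2,"Penalver et al."
"Amber from Arino, Teruel, Spain","Early Albian (Early Cretaceous)","Agathis-like (Araucariaceae)",agathis_like,amber,,,1128,False,100,"Own data"
"Amber from Doumanga, Congo","Middle Aptian","Agathoxylon sp. (Araucariaceae) or Cheirolepidiaceae",agathis_like,amber,,,2550,True,47,"Bouju and Perrichot; own data 2025"
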
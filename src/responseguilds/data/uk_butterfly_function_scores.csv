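species,biomass,biomass_qual,cultural,pollination,pollination_qual,p_brassicaceae,p_brassicaceae_qual,p_caryophyllaceae,p_caryophyllaceae_qual
Aglais io,0.125,,0.699,0.116,,0.074,,0,
Aglais urticae,0.121,,0.396,0.21,,0.138,,0,
Anthocharis cardamines,0.0005,lt,0,0.0005,lt,0.0005,gt,0,
Aphantopus hyperantus,0.25,,0.326,0.19,,0,,0,
Argynnis adippe,,na,0,,na,,na,,na
Argynnis aglaja,0.0005,lt,0,0.0005,lt,0,,0,
Argynnis paphia,0.002,,0,0.002,,0,,0,
Aricia agestis,0.0005,lt,0,0.0005,lt,0,,0.001,
Aricia artaxerxes,0.0005,lt,0,0.0005,lt,0,,0,
Boloria euphrosyne,0.0005,lt,0,0.0005,lt,0,,0.0005,gt
Boloria selene,0.0005,lt,0,0.0005,lt,0,,0.0005,gt
Callophrys rubi,0.0005,lt,0,0.0005,lt,0,,0.0005,gt
Carterocephalus palaemon,,na,0,,na,,na,,na
Celastrina argiolus,0.002,,0.067,0.004,,0,,0,
Coenonympha pamphilus,0.006,,0,0.005,,0,,0.008,
Coenonympha tullia,0.0005,lt,0,0.0005,lt,0,,0,
Colias croceus,0.0005,lt,0,0.0005,lt,0,,0,
Cupido minimus,0.0005,lt,0,0.0005,lt,0,,0,
Erebia aethiops,0.0005,lt,0,0.0005,lt,0,,0,
Erynnis tages,0.0005,lt,0,0.0005,lt,0,,0.0005,gt
Euphydryas aurinia,,na,0,,na,,na,,na
Gonepteryx rhamni,0.005,,0.062,0.005,,0.003,,0,
Hamearis lucina,,na,0,,na,,na,,na
Hesperia comma,0.0005,lt,0,0.0005,lt,0,,0,
Hipparchia semele,0.0005,lt,0,0.0005,lt,0,,0,
Lasiommata megera,0.001,,0,0.001,,0,,0,
Leptidea sinapis,0.0005,lt,0,0.0005,lt,0,,0,
Limenitis camilla,0.0005,lt,0,,na,0,,0,
Lycaena phlaeas,0.003,,0.059,0.005,,0,,0,
Maniola jurtina,1,,0.911,1,,0,,0,
Melanargia galathea,0.009,,0.099,0.008,,0,,0,
Melitaea athalia,,na,0,,na,,na,,na
Neozephyrus quercus,0.0005,lt,0,,na,0,,0.0005,gt
Ochlodes sylvanus,0.011,,0.106,0.008,,0,,0.010227,
Papilio machaon britannicus,0.0005,lt,0,0.0005,lt,0,,0.0005,gt
Pararge aegeria,0.13,,0.177,0.11,,0,,0,
Pieris napi,0.25,,0.26,0.35,,0.383,,0,
Pieris brassicae,0.612,,0.923,0.627,,0.250,,0,
Pieris rapae,0.561,,0.985,0.898,,0.561,,0,
Plebejus argus,0.0005,lt,0,0.0005,lt,0.0005,gt,0,
Polygonia c-album,0.031,,0.18,0.029,,0,,0,
Polyommatus bellargus,0.0005,lt,0,,na,0,,0,
Polyommatus coridon,0.0005,lt,0,,na,0,,0,
Polyommatus icarus,0.017,,0.173,0.027,,0,,0,
Pyrgus malvae,,na,0,,na,,na,,na
Pyronia tithonus,0.355,,1,0.325,,0,,0,
Satyrium pruni,,na,0,,na,,na,,na
Satyrium w-album,0.0005,lt,0,0.0005,lt,0,,0,
Thecla betulae,0.0005,lt,0,0.0005,lt,0,,0,
Thymelicus acteon,0.0005,lt,0,0.0005,lt,0,,0,
Thymelicus lineola,,na,0,,na,0,,0,
Thymelicus sylvestris,0.018,,0,0.017,,0,,0,
Vanessa atalanta,0.068,,0.396,0.081,,0,,0,
Vanessa cardui,0.013,,0.071,,na,0,,0,
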
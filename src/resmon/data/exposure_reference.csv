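# Deterministic dietary risk assessment for every pesticide x commodity pair
# with at least one detection in the 2020 Incheon fruit/vegetable monitoring
# survey.  ARfD in mg/kg bw, ESTI and EDI in mg/kg bw/day (two significant
# figures as printed), ADI in mg/kg bw/day, aHQ and HQ in percent.  Empty
# ARfD/ESTI/aHQ cells mean no authorized acute reference dose exists for the
# pesticide, so no acute index could be computed.  Commodity abbreviations in
# the source summary are expanded to the occurrence table's full names.
# The HQ printed for myclobutanil/Aster scaber (0.0036) is inconsistent with
# its own EDI and ADI (100 x 1.1e-5 / 0.03 = 0.0367) and is kept verbatim;
# replay checks treat that single cell as a misprint.
pesticide,commodity,arfd,esti,ahq,adi,edi,hq
Alachlor,Welsh onion,,2.5e-5,,0.01,6.8e-6,0.068
Azoxystrobin,Banana,,2.9e-4,,0.2,1.5e-5,0.007
Azoxystrobin,Grape,,6.3e-4,,0.2,2.0e-5,0.010
Azoxystrobin,Spinach,,1.3e-3,,0.2,6.4e-5,0.032
Azoxystrobin,Welsh onion,,4.2e-4,,0.2,6.8e-5,0.034
Chlorantraniliprole,Welsh onion,,1.8e-4,,2,5.1e-5,0.003
Chlorfenapyr,Aster scaber,0.03,5.1e-4,1.701,0.026,8.3e-6,0.032
Chlorfenapyr,Chili pepper,0.03,1.1e-4,0.372,0.026,1.0e-5,0.039
Chlorfenapyr,Chinese chives,0.03,2.6e-4,0.865,0.026,9.8e-6,0.038
Chlorfenapyr,Crown daisy,0.03,3.1e-5,0.103,0.026,1.5e-6,0.006
Chlorfenapyr,Giant butterbur,0.03,2.4e-4,0.813,0.026,6.6e-6,0.025
Chlorfenapyr,Lettuce leaves,0.03,2.5e-3,8.411,0.026,8.2e-5,0.314
Chlorfluazuron,Chard,,4.1e-6,,0.033,1.0e-6,0.003
Diazinon,Winter-grown cabbage,0.025,1.2e-7,0.000,0.0002,3.7e-9,0.002
Diethofencarb,Pimpinella brachycarpa,,8.4e-4,,0.43,5.7e-6,0.001
Dimethoate,Welsh onion,0.02,2.7e-5,0.137,0.002,7.5e-6,0.377
Etofenprox,Apple,1,2.8e-3,0.276,0.03,1.2e-4,0.410
Etofenprox,Chinese chives,1,7.7e-4,0.077,0.03,3.8e-5,0.126
Etofenprox,Water-celery,1,3.2e-4,0.032,0.03,6.0e-6,0.020
Etofenprox,Welsh onion,1,1.4e-4,0.014,0.03,3.8e-5,0.126
Etofenprox,Winter-grown cabbage,1,1.4e-6,0.000,0.03,4.7e-8,0.000
Fenitrothion,Crown daisy,0.04,2.7e-6,0.007,0.005,1.3e-7,0.003
Fenobucarb,Aster scaber,,1.9e-4,,0.014,7.6e-6,0.055
Flubendiamide,Crown daisy,0.2,8.0e-5,0.040,0.017,1.3e-7,0.001
Flubendiamide,Perilla leaves,0.2,8.5e-4,0.427,0.017,1.1e-4,0.622
Fludioxonil,Perilla leaves,,2.3e-3,,0.4,2.2e-4,0.056
Fludioxonil,Water-celery,,6.8e-5,,0.4,2.4e-6,0.001
Fluopyram,Chili pepper,0.5,1.0e-4,0.020,0.01,9.2e-6,0.092
Fluopyram,Crown daisy,0.5,4.0e-6,0.001,0.01,1.9e-7,0.002
Fluopyram,Lettuce leaves,0.5,2.1e-4,0.042,0.01,8.7e-6,0.087
Fluopyram,Welsh onion,0.5,6.5e-6,0.001,0.01,1.8e-6,0.018
Fluquinconazole,Pimpinella brachycarpa,0.02,2.3e-4,1.171,0.002,1.6e-6,0.080
Fluquinconazole,Welsh onion,0.02,4.6e-4,2.314,0.002,1.3e-4,6.384
Hexaconazole,Aster scaber,0.25,9.3e-4,0.370,0.005,2.7e-5,0.533
Hexaconazole,Winter-grown cabbage,0.25,2.9e-6,0.001,0.005,9.7e-8,0.002
Iprodione,Perilla leaves,0.06,7.0e-4,1.169,0.06,1.1e-4,0.176
Lufenuron,Winter-grown cabbage,,1.1e-6,,0.015,3.7e-8,0.000
Methidathion,Schisandraberry,0.01,4.3e-5,0.431,0.001,1.8e-7,0.018
Myclobutanil,Aster scaber,,2.6e-4,,0.03,1.1e-5,0.0036
Paclobutrazol,Chinese chives,0.1,1.9e-4,0.195,0.022,9.6e-6,0.044
Pendimethalin,Giant butterbur,,4.5e-6,,0.13,1.5e-7,0.000
Pendimethalin,Perilla leaves,,7.6e-6,,0.13,1.2e-6,0.001
Pendimethalin,Welsh onion,,2.7e-5,,0.13,6.3e-6,0.005
Pendimethalin,Winter-grown cabbage,,3.5e-7,,0.13,1.2e-8,0.000
Penthiopyrad,Perilla leaves,,3.4e-4,,0.018,5.1e-5,0.281
Prochloraz,Banana,0.1,2.6e-4,0.285,0.01,1.3e-5,0.131
Prochloraz,Welsh onion,0.1,1.2e-3,1.209,0.01,3.3e-4,3.336
Procymidone,Chili pepper,0.1,2.2e-4,0.220,0.1,1.7e-5,0.017
Procymidone,Chinese chives,0.1,8.1e-4,0.811,0.1,3.8e-5,0.038
Procymidone,Crown daisy,0.1,5.3e-6,0.005,0.1,2.5e-7,0.000
Procymidone,Pimpinella brachycarpa,0.1,1.1e-4,0.110,0.1,5.8e-7,0.001
Procymidone,Welsh onion,0.1,1.2e-4,0.117,0.1,3.2e-5,0.032
Pyraclostrobin,Chili pepper,0.05,1.3e-4,0.267,0.03,1.2e-5,0.040
Pyridalyl,Spinach,,1.4e-2,,0.028,7.0e-4,2.495
Tebuconazole,Apple,0.3,5.5e-4,0.1843,0.03,4.0e-5,0.133
Tebuconazole,Aster scaber,0.3,2.0e-4,0.0661,0.03,8.2e-6,0.027
Tebuconazole,Chili pepper,0.3,2.3e-4,0.0760,0.03,2.0e-5,0.068
Tebuconazole,Lettuce leaves,0.3,7.1e-5,0.0238,0.03,4.2e-6,0.014
Tebufenpyrad,Perilla leaves,0.02,2.2e-4,1.0980,0.01,1.6e-5,0.162
Tebupirimfos,Perilla leaves,,8.1e-6,,0.0002,1.2e-6,0.614
Tetraconazole,Chili pepper,0.05,1.8e-4,0.3681,0.004,1.7e-5,0.413
Thifluzamide,Lettuce leaves,,5.6e-5,,0.014,3.3e-6,0.023
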
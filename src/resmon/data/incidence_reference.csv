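# Per-pesticide incidence in the 2020 Incheon fruit/vegetable monitoring
# survey: detections (> LOD) and MRL violations out of 1146 samples, the
# detected concentration range, and the range of applicable MRLs across the
# commodities in which the pesticide was found.  Function classes:
# F fungicide, G growth regulator, H herbicide, I insecticide.
# Single-value ranges are written with conc_min == conc_max.
pesticide,function_class,n_detected,pct_detected,n_above,pct_above,conc_min,conc_max,mrl_min,mrl_max
Alachlor,H,1,0.1,0,0.0,0.038,0.038,0.05,0.05
Azoxystrobin,F,5,0.4,0,0.0,0.08,0.73,2.0,20
Chlorantraniliprole,I,1,0.1,0,0.0,0.283,0.283,2.0,2.0
Chlorfenapyr,I,13,1.1,0,0.0,0.116,1.452,1.0,5.0
Chlorfluazuron,I,1,0.1,0,0.0,0.32,0.32,5.0,5.0
Diazinon,I,2,0.2,0,0.0,0.020,0.023,0.05,0.1
Diethofencarb,F,1,0.1,0,0.0,0.93,0.93,5.0,5.0
Dimethoate,I,1,0.1,0,0.0,0.042,0.042,0.05,0.05
Etofenprox,I,8,0.7,0,0.0,0.07,0.71,1.0,7.0
Fenitrothion,I,1,0.1,0,0.0,0.015,0.015,0.05,0.05
Fenobucarb,I,1,0.1,1,0.1,0.364,0.364,0.01,0.01
Flubendiamide,I,4,0.3,2,0.2,0.058,2.8,0.02,15
Fludioxonil,F,3,0.3,0,0.0,0.13,7.48,5.0,40
Fluopyram,F,6,0.5,0,0.0,0.010,0.130,0.04,3.0
Fluquinconazole,F,2,0.2,2,0.2,0.260,0.712,0.05,0.3
Hexaconazole,F,3,0.3,1,0.1,0.58,1.82,0.7,1.0
Iprodione,F,1,0.1,0,0.0,2.3,2.3,20,20
Lufenuron,I,1,0.1,0,0.0,0.22,0.22,1.0,1.0
Methidathion,I,1,0.1,1,0.1,0.365,0.365,0.05,0.05
Myclobutanil,F,1,0.1,0,0.0,0.51,0.51,2.0,2.0
Paclobutrazol,G,1,0.1,0,0.0,0.18,0.18,0.5,0.5
Pendimethalin,H,7,0.6,0,0.0,0.024,0.069,0.05,0.07
Penthiopyrad,F,1,0.1,0,0.0,1.1,1.1,15,15
Prochloraz,F,2,0.2,1,0.1,0.07,1.86,1.0,5.0
Procymidone,F,9,0.8,2,0.2,0.029,0.75,0.05,5.0
Pyraclostrobin,F,1,0.1,0,0.0,0.17,0.17,1.0,1.0
Pyridalyl,I,1,0.1,0,0.0,0.08,0.08,5.0,5.0
Tebuconazole,F,4,0.3,1,0.1,0.041,0.390,0.05,3.0
Tebufenpyrad,I,5,0.4,0,0.0,0.10,0.72,5.0,5.0
Tebupirimfos,I,1,0.1,0,0.0,0.027,0.027,0.05,0.05
Tetraconazole,F,1,0.1,0,0.0,0.234,0.234,1.0,1.0
Thifluzamide,F,1,0.1,0,0.0,0.032,0.032,0.05,0.05
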
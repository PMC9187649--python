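# Analytical method validation summary for the 15 pesticides selected from the
# 2020 Incheon fruit/vegetable monitoring survey (calibration linearity R^2,
# LOD/LOQ in mg/kg, mean recovery in %, precision as RSD in %).
pesticide,r_squared,lod,loq,recovery_pct,rsd_pct
Azoxystrobin,0.9982,0.013,0.041,85.3,4.3
Chlorfenapyr,0.9947,0.012,0.035,98.3,3.5
Etofenprox,0.9963,0.005,0.015,97.8,2.9
Fenobucarb,0.9998,0.017,0.051,95.3,3.2
Flubendiamide,0.9986,0.012,0.035,88.3,2.6
Fludioxonil,0.9995,0.023,0.071,89.7,5.3
Fluopyram,0.9993,0.022,0.067,92.6,4.8
Fluquinconazole,0.9999,0.009,0.027,96.4,2.5
Hexaconazole,0.9967,0.040,0.120,86.1,6.4
Methidathion,0.9997,0.007,0.021,92.4,2.1
Pendimethalin,0.9978,0.004,0.012,95.6,1.3
Prochloraz,0.9997,0.013,0.038,90.9,5.9
Procymidone,0.9988,0.014,0.043,89.7,5.2
Tebuconazole,0.9996,0.004,0.011,91.1,0.5
Tebufenpyrad,0.9990,0.018,0.055,90.1,5.8
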
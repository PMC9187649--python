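# Per-commodity occurrence of pesticide residues in the 2020 Incheon
# fruit/vegetable monitoring survey: samples analysed, samples without
# detectable residue, samples with residue at or below the MRL, and samples
# with residue above the MRL.  Percentages as printed in the survey summary:
# the percentage beside the below-MRL count is the ANY-residue rate,
# (n_below + n_above) / n_total.
group,product,n_total,n_without,pct_without,n_below,pct_with,n_above,pct_above
vegetable,Aster scaber,46,37,80.4,6,19.6,3,6.5
vegetable,Chard,29,28,96.6,1,3.4,0,0.0
vegetable,Chili pepper,42,35,83.3,7,16.7,0,0.0
vegetable,Chinese chives,49,43,87.8,6,12.2,0,0.0
vegetable,Crown daisy,78,72,92.3,4,7.7,2,2.6
vegetable,Giant butterbur,9,4,44.4,5,55.6,0,0.0
vegetable,Lettuce leaves,171,164,95.9,7,4.1,0,0.0
vegetable,Perilla leaves,114,101,88.6,13,11.4,0,0.0
vegetable,Pimpinella brachycarpa,36,31,86.1,2,13.9,3,8.3
vegetable,Spinach,132,130,98.5,2,1.5,0,0.0
vegetable,Water-celery,79,75,94.9,4,5.1,0,0.0
vegetable,Welsh onion,106,93,87.7,11,12.3,2,1.9
vegetable,Winter-grown cabbage,158,152,96.2,6,3.8,0,0.0
fruit,Apple,22,19,86.4,3,13.6,0,0.0
fruit,Banana,18,16,88.9,2,11.1,0,0.0
fruit,Grape,20,19,95.0,1,5.0,0,0.0
fruit,Mandarin,9,9,100.0,0,0.0,0,0.0
fruit,Pear,14,14,100.0,0,0.0,0,0.0
fruit,Persimmon,8,8,100.0,0,0.0,0,0.0
fruit,Schisandraberry,6,5,83.3,0,16.7,1,16.7
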
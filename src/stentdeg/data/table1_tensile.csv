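# Tensile properties of pre-stretched PLLA specimens after in vitro degradation.
# Grid: pre-stretch 0/20/40% (engineering strain) x 3/10/20/30 days.
# Units: elastic_modulus_MPa in MPa; elongation_at_break dimensionless (engineering strain).
pre_stretch,time_days,elastic_modulus_MPa,elongation_at_break
0.0,3,1684.42,1.09927
0.0,10,1590.85,1.04615
0.0,20,1588.17,1.0501
0.0,30,1606.68,0.989781
0.2,3,1621.48,1.00152
0.2,10,1487.53,0.555209
0.2,20,1515.71,0.490494
0.2,30,1498.94,0.321673
0.4,3,1575.15,0.633277
0.4,10,1468.86,0.619832
0.4,20,1514.06,0.36437
0.4,30,1527.57,0.272941
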
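name,formula,charge
glucose,C6H12O6,0
glycerol,C3H8O3,0
lactate,C3H5O3,-1
pyruvate,C3H3O3,-1
acetate,C2H3O2,-1
formate,CHO2,-1
ethanol,C2H6O,0
isobutanol,C4H10O,0
succinate,C4H4O4,-2
butanediol,C4H10O2,0
butanol,C4H10O,0
co2,CO2,0
xylose,C5H10O5,0
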
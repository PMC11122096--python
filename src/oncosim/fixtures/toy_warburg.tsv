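# Toy Warburg network (synthetic): glycolysis-to-lactate vs crowding-expensive
# oxidative ATP production.  Fluxes in umol/mgDW/h, crowding in mg/mgDW per
# unit flux; biomass flux doubles as the growth rate in 1/h.
# C_enz: 0.078
# biomass: BIOMASS
# lactate: LAC_out
# glucose_uptake: GLC_up
reaction	equation	lb	ub	crowding
GLC_up	-> glc	0	1.2	0.001
GLYC	glc -> 2 pyr + 2 atp	0	1000	0.01
OXPHOS	pyr -> 15 atp	0	1000	0.25
LDH	pyr -> lac	0	1000	0.005
LAC_out	lac ->	0	1000	0.001
BIOMASS	2 glc + 60 atp ->	0	1000	0.02
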
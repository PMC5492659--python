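# mirberry bundled nearest-neighbor energy model, version 1
# Stack energy for two adjacent base pairs p=(a,b) stacked on q=(c,d):
#   E_stack = -stack_scale * (bond(p) + bond(q))   [kcal/mol]
# bond() is the hydrogen-bond weight of a pair class. Hairpin loops of
# unpaired length L (>= min_loop) are penalised by
#   min(hairpin_base + hairpin_slope * (L - min_loop), hairpin_cap)
# Interior loops, bulges and multiloop junctions carry no penalty.
# Both the dynamic program and the exhaustive-enumeration oracle read
# this file; they must never disagree on the energy of a structure.
param	value
bond_AU	2.0
bond_CG	3.0
bond_GU	1.0
stack_scale	0.5
hairpin_base	3.0
hairpin_slope	0.1
hairpin_cap	5.0
min_loop	3
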
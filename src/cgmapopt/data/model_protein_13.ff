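# 13-bead hairpin model protein -- SYNTHETIC qualitative stand-in parameter set.
# Chain of 13 beads: two 6-bead strands joined by a turn bead, with
# attractive Lennard-Jones contacts pairing the strands and purely
# repulsive cores elsewhere. Units: energy in kT at beta=1, length in
# bond lengths. Edit freely; the package parses this file at run time.
natoms 13
atom 0 0.000000 0.000000 0.000000
atom 1 1.000000 0.000000 0.000000
atom 2 2.000000 0.000000 0.000000
atom 3 3.000000 0.000000 0.000000
atom 4 4.000000 0.000000 0.000000
atom 5 5.000000 0.000000 0.000000
atom 6 5.500000 0.866025 0.000000
atom 7 5.000000 1.732051 0.000000
atom 8 4.000000 1.732051 0.000000
atom 9 3.000000 1.732051 0.000000
atom 10 2.000000 1.732051 0.000000
atom 11 1.000000 1.732051 0.000000
atom 12 0.000000 1.732051 0.000000
bond 0 1 100.0 1.0
bond 1 2 100.0 1.0
bond 2 3 100.0 1.0
bond 3 4 100.0 1.0
bond 4 5 100.0 1.0
bond 5 6 100.0 1.0
bond 6 7 100.0 1.0
bond 7 8 100.0 1.0
bond 8 9 100.0 1.0
bond 9 10 100.0 1.0
bond 10 11 100.0 1.0
bond 11 12 100.0 1.0
angle 0 1 2 2.0 180.0000
angle 1 2 3 2.0 180.0000
angle 2 3 4 2.0 180.0000
angle 3 4 5 2.0 180.0000
angle 4 5 6 2.0 120.0000
angle 5 6 7 2.0 120.0000
angle 6 7 8 2.0 120.0000
angle 7 8 9 2.0 180.0000
angle 8 9 10 2.0 180.0000
angle 9 10 11 2.0 180.0000
angle 10 11 12 2.0 180.0000
lj 0 12 3.0 1.543082 attract
lj 1 11 3.0 1.543082 attract
lj 2 10 3.0 1.543082 attract
lj 3 9 3.0 1.543082 attract
lj 4 8 3.0 1.543082 attract
lj 0 3 1.0 1.0 repel
lj 0 4 1.0 1.0 repel
lj 0 5 1.0 1.0 repel
lj 0 6 1.0 1.0 repel
lj 0 7 1.0 1.0 repel
lj 0 8 1.0 1.0 repel
lj 0 9 1.0 1.0 repel
lj 0 10 1.0 1.0 repel
lj 0 11 1.0 1.0 repel
lj 1 4 1.0 1.0 repel
lj 1 5 1.0 1.0 repel
lj 1 6 1.0 1.0 repel
lj 1 7 1.0 1.0 repel
lj 1 8 1.0 1.0 repel
lj 1 9 1.0 1.0 repel
lj 1 10 1.0 1.0 repel
lj 1 12 1.0 1.0 repel
lj 2 5 1.0 1.0 repel
lj 2 6 1.0 1.0 repel
lj 2 7 1.0 1.0 repel
lj 2 8 1.0 1.0 repel
lj 2 9 1.0 1.0 repel
lj 2 11 1.0 1.0 repel
lj 2 12 1.0 1.0 repel
lj 3 6 1.0 1.0 repel
lj 3 7 1.0 1.0 repel
lj 3 8 1.0 1.0 repel
lj 3 10 1.0 1.0 repel
lj 3 11 1.0 1.0 repel
lj 3 12 1.0 1.0 repel
lj 4 7 1.0 1.0 repel
lj 4 9 1.0 1.0 repel
lj 4 10 1.0 1.0 repel
lj 4 11 1.0 1.0 repel
lj 4 12 1.0 1.0 repel
lj 5 8 1.0 1.0 repel
lj 5 9 1.0 1.0 repel
lj 5 10 1.0 1.0 repel
lj 5 11 1.0 1.0 repel
lj 5 12 1.0 1.0 repel
lj 6 9 1.0 1.0 repel
lj 6 10 1.0 1.0 repel
lj 6 11 1.0 1.0 repel
lj 6 12 1.0 1.0 repel
lj 7 10 1.0 1.0 repel
lj 7 11 1.0 1.0 repel
lj 7 12 1.0 1.0 repel
lj 8 11 1.0 1.0 repel
lj 8 12 1.0 1.0 repel
lj 9 12 1.0 1.0 repel
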
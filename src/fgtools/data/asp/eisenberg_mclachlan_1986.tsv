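# Atomic solvation parameters, cal mol^-1 A^-2.
# Source: D. Eisenberg & A. D. McLachlan, "Solvation energy in protein
# folding and binding", Nature 319, 199-203 (1986), Table 1.
# Positive = exposure unfavourable (burial stabilises); negative = exposure
# favourable. Energy of an atom = parameter x accessible area.
carbon	16
neutral_N	-6
neutral_O	-6
charged_O	-24
charged_N	-50
sulfur	21
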
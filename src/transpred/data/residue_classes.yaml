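# Eleven physico-chemical residue classes used by the PHC encoder.
# Note: the polar and neutral sets are identical in the published class
# table; the loader warns once about this and users may substitute a
# corrected neutral set here.
charged: [D, E, K, H, R]
aliphatic: [I, L, V]
aromatic: [F, H, W, Y]
polar: [D, E, R, K, Q, N]
neutral: [D, E, R, K, Q, N]
hydrophobic: [C, V, L, I, M, F, W]
positively_charged: [H, K, R]
negatively_charged: [D, E]
tiny: [A, C, D, G, S, T]
small: [E, H, I, L, K, M, N, P, Q, V]
large: [F, R, W, Y]
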
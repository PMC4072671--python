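"""Encode a handful of protein sequences with every descriptor scheme.

Builds three short sequences in memory, runs the five encoders plus the
AAI+PSSM hybrid, and prints the dimensions and a few components. The
composition encoders report percentages (AAC and DPC each sum to 100);
the biochemical (AAI) and profile (PSSM) encoders report values in [0, 1].
"""

import transpred as tp

sequences = [
    tp.ProteinSequence("kinase_like", "MKKLLVAAGLLSDEEVRKHHGG"),
    tp.ProteinSequence("acidic", "DDEEDDEEDDEEGGSS"),
    tp.ProteinSequence("hydrophobic", "LLIIVVFFWWMMCCAA"),
]

table = tp.load_property_table()
classes = tp.load_residue_classes()

for seq in sequences:
    aac = tp.encode_aac(seq)
    dpc = tp.encode_dpc(seq)
    phc = tp.encode_phc(seq, classes)
    aai = tp.encode_aai(seq, table)
    pssm = tp.encode_pssm(tp.sample_pssm(seq, conservation=0.9, seed=7))
    hybrid = tp.encode_hybrid([aai, pssm])
    print(f"\n{seq.id} (L={len(seq)})")
    print(f"  AAC  dim={len(aac)}  sum={aac.values.sum():.1f}  "
          f"top residue={aac.names[aac.values.argmax()]} "
          f"({aac.values.max():.1f}%)")
    print(f"  DPC  dim={len(dpc)}  sum={dpc.values.sum():.1f}")
    print(f"  PHC  dim={len(phc)}  charged={phc.values[0]:.1f}%")
    print(f"  AAI  dim={len(aai)}  range=[{aai.values.min():.3f}, "
          f"{aai.values.max():.3f}]")
    print(f"  PSSM dim={len(pssm)}  range=[{pssm.values.min():.2f}, "
          f"{pssm.values.max():.2f}]")
    print(f"  AAI+PSSM hybrid dim={len(hybrid)}")

print("\nEach vector is a fixed-length numeric summary of one sequence; "
      "hybrids concatenate encoders and feed the SVMs downstream.")
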
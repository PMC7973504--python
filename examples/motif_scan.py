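"""EVI1 binding-site scan over a simulated 5 kb promoter window.

Plants the C-terminal EVI1 site (GAAGATGAG) 2500 bp into a random 5000
bp upstream window and scans all three EVI1 motifs, mirroring how a
candidate regulatory site is located upstream of a miRNA gene.
"""

from mirprot import EVI1_MOTIFS, scan
from mirprot.synthetic import simulate_promoter

window = simulate_promoter(5000, EVI1_MOTIFS["c_terminal"],
                           plant_position=2500, seed=6)
for name, hits in scan(window, EVI1_MOTIFS, top_k=1).items():
    best = hits.iloc[0]
    print(f"{name:11s} ({EVI1_MOTIFS[name]}): best hit at "
          f"{int(best['position'])} bp with {int(best['matches'])}/"
          f"{int(best['motif_length'])} matches")
print("The planted C-terminal site is found as a perfect 9/9 match at "
      "2500 bp; the other motifs only reach chance-level partial matches.")
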
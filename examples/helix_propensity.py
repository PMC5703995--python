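"""Relative amino-acid occupancy R_aa,loc near helix N-termini.

Builds a small synthetic structure set in which serine is deliberately
over-represented at the first helical position, then tallies
R_aa,loc = P_aa,loc / P_aa,all - 1.
"""

from cysredox import propensity_table
from cysredox.structure import HelixRecord
from cysredox.synth import make_ideal_helix

structures = []
for i, first in enumerate("SSSCAAAA"):  # Ser starts 3 of 8 helices
    st = make_ideal_helix(first + "AAAAAAAAA" + "CS"[i % 2] + "AAAA",
                          structure_id=f"syn{i}")
    st.helices = [HelixRecord(chain_id="A", start=1, end=10)]
    structures.append(st)

table = propensity_table(structures)
for aa in "SCA":
    row = table.query(f"aa == '{aa}' and location == 'NT1'").iloc[0]
    print(f"R_{aa},NT1 = {row['R_aa_loc']:+.2f}  "
          f"(P_loc {row['P_aa_loc']:.1f}%, P_all {row['P_aa_all']:.1f}%)")
# Positive R marks enrichment at the helix N-terminus, negative depletion;
# the tally is purely positional and ignores accessibility.
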
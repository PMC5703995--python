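"""Charge environment around modified cysteines, with planted ground truth.

Generates a synthetic S-palmitoylation dataset in which each modified
cysteine's 21-residue window carries a +0.05 per-position basic excess,
then recovers the excess, the Mann-Whitney separation and the per-protein
ratio from the sequence analysis alone.
"""

import numpy as np

from cysredox import (GeneratorConfig, build_mod_nul_sets, charge_profiles,
                      mann_whitney_two_tailed, net_charge,
                      per_protein_charge_comparison)
from cysredox.synth import generate_ptm_dataset

cfg = GeneratorConfig(seed=11, n_proteins=500, n_mod_per_protein=2,
                      delta=0.05, place_ubiquitination=False)
records, truth = generate_ptm_dataset(cfg)
mod, nul = build_mod_nul_sets(records, cfg.modification_type)
_, _, diff = charge_profiles(mod, nul)
off_centre = np.r_[diff[:10], diff[11:]]
print(f"windows: {len(mod)} MOD, {len(nul)} NUL")
print(f"planted per-position basic excess {cfg.delta:+.3f}, "
      f"recovered {off_centre.mean():+.3f}")

mw = mann_whitney_two_tailed([net_charge(w.window) for w in mod],
                             [net_charge(w.window) for w in nul])
print(f"window net charge MOD vs NUL: U = {mw.u:.0f}, p = {mw.p_value:.2e}")

strong = GeneratorConfig(seed=12, n_proteins=500, delta=0.5,
                         enriched_protein_fraction=0.8,
                         place_ubiquitination=False)
records, _ = generate_ptm_dataset(strong)
out = per_protein_charge_comparison(records, strong.modification_type)
print(f"per-protein comparison: {out['greater']}:{out['not_greater']} "
      f"(ratio {out['ratio']:.1f}:1) favour a more positive MOD surround")
# A ratio near 4:1 mirrors the planted 80% of proteins with basic-enriched
# modification windows.
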
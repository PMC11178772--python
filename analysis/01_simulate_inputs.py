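"""Generate the synthetic study inputs for the downstream analyses.

Writes, under results/inputs/:
  * fibrin_like.fasta — three chains with cleavage motifs planted at the
    canonical author positions (Aα-like 162 & 171, Bβ-like 346, γ-like 406);
  * pose_*.pdb — seven docked enzyme–peptide poses with SG–C planted at
    the six reported docking distances (4.6, 4.9, 4.3, 4.2, 4.4, 4.3 Å)
    plus a 7.0 Å negative control;
  * clot_assay.tsv — clot-lysis replicates with planted dose ordering
    (12 / 55 / 73 % mean degradation, SD 2, n = 3).

Trajectories are bulky and are regenerated in memory by
05_trajectory_analysis.py rather than stored.
"""

import sys
from pathlib import Path

import pandas as pd

from fibryze.io import write_fasta, write_pdb
from fibryze.synth import gen_clot_table, gen_pose, gen_preset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

chains = gen_preset("fibrin-like", seed=SEED)
write_fasta(chains, OUT / "fibrin_like.fasta")
print(f"wrote {len(chains)} fibrin-like chains "
      f"({', '.join(f'{c.id}:{len(c)} aa' for c in chains)})")

POSE_DISTANCES = {
    "Aa1": 4.6, "Aa2": 4.9, "Aa3": 4.3, "Bb1": 4.2, "g1": 4.4, "g2": 4.3,
    "negative_control": 7.0,
}
for name, sg_c in POSE_DISTANCES.items():
    write_pdb(gen_pose(sg_c, n_hbonds=0), OUT / f"pose_{name}.pdb")
print(f"wrote {len(POSE_DISTANCES)} poses with planted SG-C distances "
      f"{sorted(set(POSE_DISTANCES.values()))}")

records = gen_clot_table(seed=SEED)
pd.DataFrame([r.__dict__ for r in records]).to_csv(OUT / "clot_assay.tsv", sep="\t", index=False)
print(f"wrote clot assay table: {len(records)} replicates in 3 dose groups")
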
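"""Parse a proteinGroups-style table and watch the filtering rules act.

Builds a small tab-separated file in the MaxQuant dialect (a stored 0 LFQ
intensity means "not quantified"), parses it, and shows which records the
identification filter and the imputation stage dismiss, and why.
"""

import tempfile
from pathlib import Path

from ipenrich import AnalysisConfig, read_protein_groups, run_pipeline

HEADER = ("Protein IDs\tGene names\tRazor + unique peptides\t"
          "LFQ intensity bait\tLFQ intensity control\t"
          "Potential contaminant\tReverse\tOnly identified by site")
ROWS = [
    "P10000\tTRRAP\t42\t8.1e8\t0\t\t\t",        # strong bait-only candidate
    "P20000\tACTB\t30\t5.0e9\t4.8e9\t\t\t",     # abundant background
    "P30000\tKRT1\t12\t2.0e8\t1.9e8\t+\t\t",    # contaminant flag
    "REV__P4\t\t8\t1.0e7\t9.0e6\t\t+\t",        # decoy
    "P50000\tGENE5\t1\t3.0e6\t0\t\t\t",         # single peptide
    "P60000\tGENE6\t2\t4.0e6\t0\t\t\t",         # missing control, 2 peptides
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "protein_groups.tsv"
    path.write_text("\n".join([HEADER, *ROWS]) + "\n")
    table = read_protein_groups(path)
    print(f"parsed {len(table)} protein groups")
    for rec in table:
        print(f"  {rec.protein_ids:<9} peptides={rec.peptides_razor_unique:>2} "
              f"bait={'yes' if rec.lfq_bait else 'no ':<3} "
              f"control={'yes' if rec.lfq_control else 'no'}")
    result = run_pipeline(table, AnalysisConfig(rng_seed=0))
    print(f"\nsurvived: {[r.protein_ids for r in result.records]}")
    print("dismissed:")
    for d in result.dismissals:
        print(f"  {d.protein_ids:<9} [{d.stage}] {d.reason}")
# TRRAP survives with an imputed control (42 peptides >= 3); the
# contaminant, the decoy, the single-peptide protein and the two-peptide
# missing-control protein are logged with their dismissal reasons.
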
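"""Validate expression changes at the mRNA level with 2^-ddCt qPCR.

Reference-gene stability is checked first; target genes are normalised to
the mean of the two reference genes and calibrated to group I.
"""

from common import CONFIG, RUN_DIR
from radprot import io, pipeline

results = pipeline.stage_qpcr(CONFIG, RUN_DIR)
stab = io.read_tsv(RUN_DIR / "reference_stability.tsv")
print("reference genes:",
      ", ".join(f"{r.gene} sd={r.sd_ct:.2f} ({'ok' if r.stable else 'UNSTABLE'})"
                for r in stab.itertuples()))
for row in results[results["group"] != "I"].itertuples():
    flag = "*" if row.p == row.p and row.p <= 0.05 else " "
    print(f"{row.gene} group {row.group}: fold {row.mean_fold:.2f} "
          f"+/- {row.sem:.2f} (n={row.n}, p={row.p:.3g}){flag}")
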
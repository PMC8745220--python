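"""Shared fixture builder: expression matrix with the published group means.

Each gene gets four case and four control samples placed symmetrically
around the published log2 group means, so the sample means equal the
printed values exactly while the within-group SD stays positive.
"""

from pathlib import Path

PRINTED_TABLE = [
    # gene, case mean, control mean, printed |FC|, direction
    ("AFF1", 9.95, 8.84, 2.17, "up"),
    ("ALDH1L1", 6.03, 7.23, 2.29, "down"),
    ("ARL11", 3.11, 2.07, 2.06, "up"),
    ("BATF", 10.52, 8.94, 2.99, "up"),
    ("CAMK2G", 6.80, 8.01, 2.31, "down"),
    ("CD86", 14.38, 11.30, 8.48, "up"),
    ("DOCK10", 8.71, 10.01, 2.47, "down"),
    ("IL20RA", 7.57, 5.97, 3.00, "up"),
    ("KCNIP1", 3.84, 2.65, 2.28, "up"),
    ("LEF1", 7.64, 6.29, 2.55, "up"),
    ("LINC01108", 2.09, 3.17, 2.12, "down"),
    ("LOC100130476", 3.33, 2.16, 2.24, "up"),
    ("NR1D1", 8.31, 6.45, 3.63, "up"),
    ("SMARCA4", 14.07, 12.12, 3.86, "up"),
    ("TEF", 9.02, 7.76, 2.40, "up"),
    ("TMEM130", 6.73, 7.94, 2.32, "down"),
    ("TMEM47", 9.60, 10.70, 2.21, "down"),
    ("TTC28", 8.72, 7.52, 2.30, "up"),
]


def write_printed_expression(path: Path, spread: float = 0.05) -> None:
    samples = [f"MS{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 5)]
    groups = ["case"] * 4 + ["control"] * 4
    with Path(path).open("w") as fh:
        fh.write("gene_id\t" + "\t".join(samples) + "\n")
        fh.write("group\t" + "\t".join(groups) + "\n")
        for gene, m1, m0, _fc, _d in PRINTED_TABLE:
            vals = [m1 - spread, m1 + spread, m1 - spread, m1 + spread]
            vals += [m0 - spread, m0 + spread, m0 - spread, m0 + spread]
            fh.write(gene + "\t" + "\t".join(repr(v) for v in vals) + "\n")
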
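"""Differential expression between case and control samples.

Per-gene statistics on a log2 expression matrix: group means and SDs,
empirical-Bayes moderated t-test (per-gene variances shrunk toward a prior
fitted by moment matching on the log sample variances), Benjamini-Hochberg
adjustment, absolute linear-scale fold change 2^|dmean|, and the
FC >= 2 / p <= 0.05 selection rule (both boundaries inclusive).

The moderated test pools the two group variances into s_g^2 with
d_g = n1 + n0 - 2 degrees of freedom, replaces it by the posterior
(d0*s0^2 + d_g*s_g^2) / (d0 + d_g), and refers
t = dmean / sqrt(post * (1/n1 + 1/n0)) to a t distribution on d0 + d_g
degrees of freedom.  With shrinkage disabled (``shrink=None``) it reduces
exactly to the ordinary pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CASE, CONTROL, ExpressionMatrix, ValidationError

logger = logging.getLogger("varfunnel")

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class ShrinkageParams:
    """Empirical-Bayes prior for gene variances.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the observed
    log-variances show no excess spread over pure sampling noise) and
    ``s0_sq`` the prior variance in squared log2 units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("prior df d0 must be positive (or infinite)")
        if not (self.s0_sq > 0):
            raise ValidationError("prior variance s0_sq must be positive")


@dataclass
class DERecord:
    gene_id: str
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    t_stat: float
    df: float
    p_raw: float
    p_adj: float
    fold_change: float
    direction: str
    degenerate: bool = False  # zero pooled variance handled by limit convention


def fold_change(mean_case: float, mean_control: float) -> tuple[float, str]:
    """Absolute linear fold change and direction from log2 group means.

    FC = 2^|mean_case - mean_control| (>= 1); direction is "up" when the
    case mean is higher, with the exact tie broken as "up".
    """
    if not (math.isfinite(mean_case) and math.isfinite(mean_control)):
        raise ValidationError("fold_change requires finite inputs")
    delta = mean_case - mean_control
    return 2.0 ** abs(delta), UP if delta >= 0 else DOWN


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, strictly decreasing and convex on (0, inf), so the
    Newton step on 1/trigamma converges monotonically from the asymptotic
    start x = 1/y + 0.5.
    """
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if y > 1e7:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / math.sqrt(y)
    if y < 1e-8:  # trigamma(x) ~ 1/x as x -> inf
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_shrinkage(sample_variances: np.ndarray, dg: float | np.ndarray) -> ShrinkageParams:
    """Moment-match the scaled inverse-chi-square prior for gene variances.

    Works on e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2), whose mean and
    excess variance over the trigamma sampling term identify s0^2 and d0.
    Zero-variance genes are excluded from the fit (logged); at least 10
    positive-variance genes are required.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    dg_arr = np.broadcast_to(np.asarray(dg, dtype=float), s2.shape)
    pos = s2 > 0
    if not pos.any():
        raise ValidationError("all gene variances are zero; cannot fit a prior")
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("fit_shrinkage: excluded %d zero-variance genes", n_zero)
    s2, dg_arr = s2[pos], dg_arr[pos]
    if s2.size < 10:
        raise ValidationError(
            f"need >= 10 genes with positive variance to fit shrinkage, got {s2.size}"
        )
    e = np.log(s2) - special.digamma(dg_arr / 2.0) + np.log(dg_arr / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, dg_arr / 2.0)))
    if excess <= 0:
        return ShrinkageParams(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ShrinkageParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    matrix: ExpressionMatrix, shrink: ShrinkageParams | None = None
) -> list[DERecord]:
    """Per-gene moderated (or, with ``shrink=None``, ordinary pooled) t-test.

    Returns one :class:`DERecord` per gene in input order, with BH-adjusted
    p-values computed across all genes.  Genes with zero pooled variance and
    no shrinkage fall back to the limit convention (p = 0 when the means
    differ, p = 1 otherwise) and are flagged ``degenerate``.
    """
    case_idx = matrix.group_columns(CASE)
    ctrl_idx = matrix.group_columns(CONTROL)
    n1, n0 = len(case_idx), len(ctrl_idx)
    x1 = matrix.values[:, case_idx]
    x0 = matrix.values[:, ctrl_idx]
    mean1, mean0 = x1.mean(axis=1), x0.mean(axis=1)
    var1 = x1.var(axis=1, ddof=1)
    var0 = x0.var(axis=1, ddof=1)
    dg = n1 + n0 - 2
    pooled = ((n1 - 1) * var1 + (n0 - 1) * var0) / dg
    delta = mean1 - mean0
    scale = 1.0 / n1 + 1.0 / n0

    if shrink is None:
        post_var = pooled
        df_total = float(dg)
    elif math.isinf(shrink.d0):
        post_var = np.full_like(pooled, shrink.s0_sq)
        df_total = math.inf
    else:
        post_var = (shrink.d0 * shrink.s0_sq + dg * pooled) / (shrink.d0 + dg)
        df_total = shrink.d0 + dg

    t = np.zeros_like(delta)
    p = np.ones_like(delta)
    degenerate = post_var <= 0
    ok = ~degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        t[ok] = delta[ok] / np.sqrt(post_var[ok] * scale)
    if math.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
    # limit convention for zero pooled variance without a prior
    nonzero_delta = degenerate & (delta != 0)
    t[nonzero_delta] = np.sign(delta[nonzero_delta]) * np.inf
    p[nonzero_delta] = 0.0
    if degenerate.any():
        logger.warning(
            "moderated_t: %d genes with zero variance handled by limit convention",
            int(degenerate.sum()),
        )
    # BH needs p in (0, 1]; exact zeros from the limit convention are kept
    # at zero (they remain zero after any step-up adjustment).
    p_for_adjust = np.where(p == 0.0, np.nextafter(0.0, 1.0), p)
    p_adj = benjamini_hochberg(p_for_adjust.tolist())
    p_adj = np.where(p == 0.0, 0.0, p_adj)

    records = []
    for i, gene in enumerate(matrix.gene_ids):
        fc, direction = fold_change(float(mean1[i]), float(mean0[i]))
        records.append(
            DERecord(
                gene_id=gene,
                mean_case=float(mean1[i]),
                mean_control=float(mean0[i]),
                sd_case=float(np.sqrt(var1[i])),
                sd_control=float(np.sqrt(var0[i])),
                t_stat=float(t[i]),
                df=df_total if not degenerate[i] else float(dg),
                p_raw=float(p[i]),
                p_adj=float(p_adj[i]),
                fold_change=fc,
                direction=direction,
                degenerate=bool(degenerate[i]),
            )
        )
    return records


def benjamini_hochberg(p_values: list[float]) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def select_de(
    records: list[DERecord],
    fc_min: float = 2.0,
    p_max: float = 0.05,
    use_adjusted: bool = True,
) -> list[str]:
    """Genes with fold_change >= fc_min and p <= p_max (both inclusive)."""
    out = []
    for rec in records:
        p = rec.p_adj if use_adjusted else rec.p_raw
        if rec.fold_change >= fc_min and p <= p_max:
            out.append(rec.gene_id)
    return out


def write_de_table(records: list[DERecord], path: str | Path) -> None:
    """Write the DE table (gene, regulation, mean +/- SD per group, FC, p)."""
    with Path(path).open("w") as fh:
        fh.write(
            "gene_id\tregulation\tmean_case\tsd_case\tmean_control\tsd_control\t"
            "fold_change\tp_raw\tp_adj\n"
        )
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.direction}\t{r.mean_case:.4f}\t{r.sd_case:.4f}\t"
                f"{r.mean_control:.4f}\t{r.sd_control:.4f}\t{r.fold_change:.4f}\t"
                f"{r.p_raw:.6g}\t{r.p_adj:.6g}\n"
            )
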
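"""Ratio normalization and per-peptide regulation testing.

SILAC treated/control ratios are transformed to log2 and median-normalized
per quantification channel (condition x replicate), so each channel's
median log2 ratio is exactly zero over the peptides quantified in it. A
peptide is then called regulated in a condition by a two-sided one-sample
t-test of its replicate log2 ratios against zero, with Benjamini–Hochberg
correction across all scored peptides.

With two replicates the t statistic has one degree of freedom, whose
two-sided tail is the standard Cauchy tail: p = 1 - (2/pi) * arctan(|t|).
Two conventions keep degenerate peptides well-defined: all replicate log2
ratios exactly zero gives p = 1 (zero effect), and zero spread around a
non-zero mean gives p = 0 (infinite t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import CHANNELS, CONDITIONS, REPLICATES, PhosphoPeptideRecord

logger = logging.getLogger(__name__)


def log2_column(condition: str, replicate: int) -> str:
    return f"log2_{condition}_r{replicate}"


def mean_column(condition: str) -> str:
    return f"mean_log2_{condition}"


@dataclass
class RegulationTable:
    """Per-peptide normalized log2 ratios and regulation calls.

    ``data`` is indexed by ``peptide_id`` with columns
    ``log2_<condition>_r<replicate>`` and ``mean_log2_<condition>``;
    after :func:`test_regulation` also ``p_nom``, ``p_adj``,
    ``significant``, ``direction`` and ``scored`` for the tested
    condition (recorded in ``condition`` / ``alpha``).
    """

    data: pd.DataFrame
    condition: str | None = None
    alpha: float | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def significant_ids(self) -> set[str]:
        if "significant" not in self.data:
            return set()
        return set(self.data.index[self.data["significant"].fillna(False)])

    def nominally_regulated_ids(self, alpha: float = 0.05) -> set[str]:
        """Peptides with nominal p below ``alpha`` (the volcano's p < 0.05 set)."""
        return set(self.data.index[self.data["p_nom"] < alpha])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="peptide_id")

    def volcano_frame(self) -> pd.DataFrame:
        """Mean log2 fold change vs -log10 nominal p, with significance flags."""
        cond = self.condition
        out = pd.DataFrame(
            {
                "mean_log2": self.data[mean_column(cond)],
                "neg_log10_p_nom": -np.log10(self.data["p_nom"]),
                "significant": self.data["significant"].fillna(False),
                "direction": self.data["direction"],
            }
        )
        return out


def normalize_ratios(records: list[PhosphoPeptideRecord]) -> RegulationTable:
    """Median-normalize SILAC ratios in log2 space, per channel.

    Channels with no quantified peptide are skipped with a warning.
    Missing cells stay missing (NaN).
    """
    index = [rec.peptide_id for rec in records]
    data = pd.DataFrame(index=pd.Index(index, name="peptide_id"), dtype=float)
    for cond, rep in CHANNELS:
        col = [rec.ratios.get((cond, rep), np.nan) for rec in records]
        data[log2_column(cond, rep)] = np.log2(np.asarray(col, dtype=float))

    for cond, rep in CHANNELS:
        col = log2_column(cond, rep)
        values = data[col]
        if values.notna().sum() == 0:
            logger.warning("channel %s/r%d has no quantified peptides; skipped",
                           cond, rep)
            continue
        data[col] = values - values.median()

    for cond in CONDITIONS:
        reps = [log2_column(cond, r) for r in REPLICATES]
        data[mean_column(cond)] = data[reps].mean(axis=1)

    return RegulationTable(data=data)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-peptide variances.

    Fits a scaled-F prior to the observed sample variances (moment
    matching on log variances) and returns the posterior variances and
    the prior degrees of freedom. With few replicates per peptide this
    borrows strength across the whole table, the standard moderated-test
    device for two-replicate designs.
    """
    from scipy.special import polygamma, psi

    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[ok])
    e = z - float(psi(df / 2.0)) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        post = np.full_like(s2, s0_sq)
    return post, d0


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test of ``values`` against 0 (n >= 2)."""
    if np.all(values == 0.0):
        return 1.0
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        return 0.0  # identical non-zero replicates: infinite t
    t = mean / (sd / np.sqrt(len(values)))
    return float(2.0 * stats.t.sf(abs(t), df=len(values) - 1))


def test_regulation(
    table: RegulationTable,
    condition: str = "CHIR_10uM",
    alpha: float = 0.05,
    method: str = "t",
) -> RegulationTable:
    """Score per-peptide regulation for one condition, in place.

    Peptides with both replicate log2 ratios present are scored; peptides
    with fewer than two replicates are flagged unscored
    (``scored = False``, p-values NaN) rather than dropped.
    ``significant`` is ``p_adj < alpha`` (Benjamini–Hochberg over scored
    peptides) and ``direction`` is the sign of the mean log2 ratio for
    significant peptides, ``"none"`` otherwise.

    ``method="t"`` is the plain one-sample t-test (one degree of freedom
    with two replicates, so deliberately conservative);
    ``method="moderated"`` shrinks per-peptide variances toward a prior
    fitted across the table before testing, recovering power in
    two-replicate designs.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if method not in ("t", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    data = table.data
    rep_cols = [log2_column(condition, r) for r in REPLICATES]
    values = data[rep_cols].to_numpy(dtype=float)
    scored = ~np.isnan(values).any(axis=1)

    p_nom = np.full(len(data), np.nan)
    if method == "t":
        for i in np.flatnonzero(scored):
            p_nom[i] = _one_sample_p(values[i])
    else:
        idx = np.flatnonzero(scored)
        vals = values[idx]
        n_rep = vals.shape[1]
        means = vals.mean(axis=1)
        s2 = vals.var(axis=1, ddof=1)
        post, d0 = _squeeze_variances(s2, df=float(n_rep - 1))
        df_total = (n_rep - 1) + d0
        with np.errstate(divide="ignore"):
            t_mod = means / np.sqrt(post / n_rep)
        if np.isfinite(df_total):
            p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
        else:
            p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
        p_mod = np.where(np.all(vals == 0.0, axis=1), 1.0, p_mod)
        p_mod = np.where(np.isinf(t_mod), 0.0, p_mod)
        p_nom[idx] = p_mod

    p_adj = np.full(len(data), np.nan)
    if scored.any():
        _, adj, _, _ = multipletests(p_nom[scored], method="fdr_bh")
        p_adj[scored] = adj

    mean_log2 = data[mean_column(condition)].to_numpy(dtype=float)
    significant = (p_adj < alpha) & scored
    direction = np.where(
        significant, np.where(mean_log2 < 0, "down", "up"), "none"
    )

    data["scored"] = scored
    data["p_nom"] = p_nom
    data["p_adj"] = p_adj
    data["significant"] = significant
    data["direction"] = direction
    table.condition = condition
    table.alpha = alpha
    return table
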
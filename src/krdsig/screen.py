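"""Two-stage signature derivation: differential expression between the
mutation-like and wildtype-like groups, then a survival screen on the
differentially expressed genes.

Stage 1 tests each gene with Welch's t on log-scale expression and keeps
genes with BH-adjusted p < 0.01 and |log2FC| > 1. Stage 2 subjects the
surviving genes to a Kaplan-Meier log-rank test (expression split at the
per-gene median) and a univariate Cox proportional-hazards fit on
standardized continuous expression; genes with BH-adjusted p < 0.05 in both
analyses are retained. The retained genes form a signed signature, the
up/down split given by the sign of the fold change.

The differential-expression test is Welch's t rather than an
empirical-Bayes moderated fit: at the sample sizes this package targets the
moderation has negligible effect and the per-gene test keeps the screen
transparent and dependency-light.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSignature, SurvivalTable

DEFAULT_LFC = 1.0
DEFAULT_Q_DE = 0.01
DEFAULT_Q_SURV = 0.05


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Adjusted values are ``min_{j >= k} p_(j) * m / j`` capped at 1, computed
    with the canonical ``p * m / rank`` scaling.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _group_arrays(
    matrix: ExpressionMatrix, labels: pd.Series | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, str, str]:
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("sample")["label"]
    labels = labels.reindex(matrix.samples)
    if labels.isna().any():
        raise ValidationError("every matrix sample needs a group label")
    names = list(dict.fromkeys(labels.tolist()))
    if len(names) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {names}")
    g1 = labels.to_numpy() == names[0]
    return g1, ~g1, names[0], names[1]


def differential_expression(
    matrix: ExpressionMatrix,
    labels: pd.Series | pd.DataFrame,
    group1: str | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-t p-value between two groups.

    ``labels`` maps sample to group (Series indexed by sample, or a frame
    with ``sample``/``label`` columns). ``log2fc`` is mean(group1) -
    mean(group2) on the log scale; ``group1`` defaults to the first label
    encountered (pass the mutation-like label explicitly for a signed
    contrast). Genes with zero variance and equal means in both groups get
    p = 1 by convention.
    """
    m1, m2, n1, n2 = _group_arrays(matrix, labels)
    if group1 is not None:
        if group1 == n2:
            m1, m2, n1, n2 = m2, m1, n2, n1
        elif group1 != n1:
            raise ValidationError(f"group {group1!r} not among labels ({n1!r}, {n2!r})")
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    a, b = matrix.values[:, m1], matrix.values[:, m2]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    out = pd.DataFrame({"gene": matrix.genes, "log2fc": lfc, "p_de": p})
    out.attrs["contrast"] = f"{n1} - {n2}"
    return out


def survival_screen(
    matrix: ExpressionMatrix,
    survival: SurvivalTable,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene survival association: KM log-rank and univariate Cox.

    For each gene, samples are split at the median expression and the two
    arms compared with a two-sided log-rank test (``p_km``); a univariate
    Cox proportional-hazards model on the per-gene standardized expression
    yields ``p_cox`` and the hazard ratio ``hr`` per expression SD (Efron
    tie handling). Constant genes are degenerate: p = 1, hr = 1.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    surv = survival.subset(matrix.samples)
    if len(surv.samples) < 10:
        raise ValidationError("survival screen needs >= 10 samples")
    if surv.n_events < 1:
        raise ValidationError("survival screen needs >= 1 event")
    gene_list = list(genes) if genes is not None else list(matrix.genes)
    idx = matrix.gene_index(gene_list)
    time, event = surv.time, surv.event

    p_km = np.empty(len(gene_list))
    p_cox = np.empty(len(gene_list))
    hr = np.empty(len(gene_list))
    cph = CoxPHFitter()
    for k, gi in enumerate(idx):
        x = matrix.values[gi]
        med = np.median(x)
        high = x > med
        if high.sum() == 0 or high.sum() == len(x):
            p_km[k], p_cox[k], hr[k] = 1.0, 1.0, 1.0
            continue
        lr = logrank_test(time[high], time[~high], event[high], event[~high])
        p_km[k] = float(lr.p_value)
        z = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"time": time, "event": event, "x": z})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            p_cox[k] = float(cph.summary.loc["x", "p"])
            hr[k] = float(np.exp(cph.params_["x"]))
        except Exception:
            warnings.warn(f"Cox fit failed for gene {gene_list[k]!r}; p set to 1")
            p_cox[k], hr[k] = 1.0, np.nan
    return pd.DataFrame(
        {"gene": gene_list, "p_km": p_km, "p_cox": p_cox, "hr": hr}
    )


def run_screen(
    matrix: ExpressionMatrix,
    labels: pd.Series | pd.DataFrame,
    survival: SurvivalTable,
    group1: str | None = None,
    lfc_threshold: float = DEFAULT_LFC,
    q_de: float = DEFAULT_Q_DE,
    q_surv: float = DEFAULT_Q_SURV,
    survival_on: str = "de_pass",
    require_both: bool = True,
    signature_name: str = "SCREEN",
) -> tuple[pd.DataFrame, GeneSignature | None]:
    """Run the full two-stage screen and assemble the retained signature.

    Returns the per-gene screen table (columns ``gene``, ``log2fc``,
    ``p_de``, ``q_de``, ``p_km``, ``q_km``, ``p_cox``, ``q_cox``, ``hr``,
    ``pass_de``, ``pass_surv``, ``retained``) and the signed signature of
    retained genes (``None``, with a warning, if nothing survives). With
    ``survival_on="de_pass"`` (the default, mirroring the two-step
    procedure) survival statistics are computed — and BH-adjusted — only
    over the genes passing the DE filter; ``"all"`` screens every gene.
    ``require_both=False`` relaxes the survival criterion to KM or Cox.
    """
    de = differential_expression(matrix, labels, group1=group1)
    de["q_de"] = bh_adjust(de["p_de"])
    de["pass_de"] = (de["q_de"] < q_de) & (de["log2fc"].abs() > lfc_threshold)

    if survival_on == "de_pass":
        surv_genes = de.loc[de["pass_de"], "gene"].tolist()
    elif survival_on == "all":
        surv_genes = de["gene"].tolist()
    else:
        raise ValidationError(f"unknown survival_on {survival_on!r}")

    table = de.set_index("gene")
    for col in ("p_km", "q_km", "p_cox", "q_cox", "hr"):
        table[col] = np.nan
    table["pass_surv"] = False
    if surv_genes:
        sv = survival_screen(matrix, survival, genes=surv_genes).set_index("gene")
        sv["q_km"] = bh_adjust(sv["p_km"])
        sv["q_cox"] = bh_adjust(sv["p_cox"])
        if require_both:
            sv["pass_surv"] = (sv["q_km"] < q_surv) & (sv["q_cox"] < q_surv)
        else:
            sv["pass_surv"] = (sv["q_km"] < q_surv) | (sv["q_cox"] < q_surv)
        table.loc[sv.index, ["p_km", "q_km", "p_cox", "q_cox", "hr", "pass_surv"]] = sv[
            ["p_km", "q_km", "p_cox", "q_cox", "hr", "pass_surv"]
        ]
        table["pass_surv"] = table["pass_surv"].astype(bool)
    table["retained"] = table["pass_de"] & table["pass_surv"]
    table = table.reset_index()[
        ["gene", "log2fc", "p_de", "q_de", "p_km", "q_km", "p_cox", "q_cox",
         "hr", "pass_de", "pass_surv", "retained"]
    ]
    table.attrs.update(
        {"lfc_threshold": lfc_threshold, "q_de": q_de, "q_surv": q_surv,
         "survival_on": survival_on, "require_both": require_both}
    )

    kept = table[table["retained"]]
    if kept.empty:
        warnings.warn("screen retained no genes; returning empty signature")
        return table, None
    up = kept.loc[kept["log2fc"] > 0, "gene"].tolist()
    down = kept.loc[kept["log2fc"] <= 0, "gene"].tolist()
    return table, GeneSignature(signature_name, up, down)
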
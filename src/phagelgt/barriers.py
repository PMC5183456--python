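"""Genetic versus ecological barriers to transduction.

Each pairwise genome-similarity measure is treated as a predictor of whether a
donor–recipient pair is connected in the dLGT network (ROC analysis); habitat
transfer counts are compared against degree-preserving null networks; and the
functional composition of transferred genes is tested against the genomic
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .datatypes import TransductionEvent
from .network import donor_recipient_pairs
from .randomize import empirical_pvalue
from .seqsim import SimilarityProfile

PREDICTORS = ("s_gs", "s_cds", "s_gc", "d_cu", "habitat_shared")


@dataclass
class RocEntry:
    predictor: str
    auc: float
    tpr: float
    fpr: float
    threshold: float
    degenerate: bool = False


@dataclass
class ROCReport:
    entries: dict[str, RocEntry] = field(default_factory=dict)

    def auc(self, predictor: str) -> float:
        return self.entries[predictor].auc


def _predictor_values(profiles: list[SimilarityProfile], predictor: str) -> np.ndarray:
    vals = []
    for p in profiles:
        v = getattr(p, predictor)
        if predictor == "habitat_shared":
            v = 1.0 if v else 0.0
        elif predictor == "d_cu":
            v = -v  # smaller distance = more similar
        if v is None:
            v = np.nan
        vals.append(float(v))
    return np.asarray(vals)


def roc_analysis(
    connected_pairs: list[SimilarityProfile],
    background_pairs: list[SimilarityProfile],
    predictors: tuple[str, ...] = PREDICTORS,
) -> ROCReport:
    """ROC analysis of each similarity measure as a predictor of connectedness.

    AUC equals the normalized Mann–Whitney rank statistic; the operating point
    maximizes Youden's J (ties broken by the lowest threshold). Codon-usage
    distance enters with its sign inverted. Pairs with an undefined value for a
    predictor are dropped for that predictor only. A constant predictor is
    reported with AUC 0.5 and flagged degenerate.
    """
    if not connected_pairs or not background_pairs:
        raise ValueError("need at least one positive and one negative pair")
    report = ROCReport()
    y = np.concatenate([np.ones(len(connected_pairs)), np.zeros(len(background_pairs))])
    for predictor in predictors:
        x = np.concatenate([
            _predictor_values(connected_pairs, predictor),
            _predictor_values(background_pairs, predictor),
        ])
        keep = ~np.isnan(x)
        xv, yv = x[keep], y[keep]
        if np.unique(xv).size < 2 or np.unique(yv).size < 2:
            report.entries[predictor] = RocEntry(predictor, 0.5, 0.0, 0.0,
                                                 float("nan"), degenerate=True)
            continue
        auc = float(roc_auc_score(yv, xv))
        fpr, tpr, thresholds = roc_curve(yv, xv)
        j = tpr - fpr
        best_j = j.max()
        # among maximal-J points choose the lowest threshold (deterministic)
        cands = np.nonzero(j >= best_j - 1e-12)[0]
        k = cands[np.argmin(thresholds[cands])]
        report.entries[predictor] = RocEntry(
            predictor, auc, float(tpr[k]), float(fpr[k]), float(thresholds[k])
        )
    return report


# --------------------------------------------------------------------------
# Habitat analysis
# --------------------------------------------------------------------------

@dataclass
class HabitatTransferMatrix:
    habitats: list[str]
    observed: pd.DataFrame                  # habitat x habitat counts (paths)
    expected: pd.DataFrame | None           # ensemble means
    pvalues: pd.DataFrame | None            # per-cell empirical p (upper tail)
    same_habitat_fraction_paths: float      # deduplicated donor->recipient paths
    same_habitat_fraction_events: float     # event-weighted
    n_pairs: int
    n_events_with_habitat: int
    n_dropped: int
    p_same_habitat: float | None = None


def _path_habitat_counts(
    net: nx.DiGraph, habitat: dict[str, str], habitats: list[str]
) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=habitats, columns=habitats, dtype=int)
    for d, r in donor_recipient_pairs(net):
        hd, hr = habitat.get(d), habitat.get(r)
        if hd is None or hr is None:
            continue
        counts.loc[hd, hr] += 1
    return counts


def habitat_transfer_analysis(
    events: list[TransductionEvent],
    habitat: dict[str, str],
    net: nx.DiGraph,
    null_networks=None,
) -> HabitatTransferMatrix:
    """Within- vs cross-habitat transfer counts with a degree-preserving null.

    The observed matrix counts distinct donor->phage->recipient paths by the
    donor and recipient habitat; the same-habitat fraction is also reported
    event-weighted. Null expectations and per-cell upper-tail empirical
    p-values come from rewired replicates (``null_networks`` iterable).
    Events whose donor or recipient lacks a habitat label are dropped and
    counted.
    """
    habitats = sorted(set(habitat.values()))
    observed = _path_habitat_counts(net, habitat, habitats)
    n_pairs = int(observed.values.sum())
    same_paths = float(np.trace(observed.values) / n_pairs) if n_pairs else 0.0

    n_evt = dropped = same_evt = 0
    for ev in events:
        if ev.donor is None:
            continue
        hd, hr = habitat.get(ev.donor), habitat.get(ev.recipient)
        if hd is None or hr is None:
            dropped += 1
            continue
        n_evt += 1
        same_evt += int(hd == hr)

    expected = pvalues = None
    p_same = None
    if null_networks is not None:
        null_counts = []
        null_same = []
        for rand in null_networks:
            c = _path_habitat_counts(rand, habitat, habitats)
            null_counts.append(c.values)
            tot = c.values.sum()
            null_same.append(np.trace(c.values) / tot if tot else 0.0)
        stack = np.stack(null_counts)
        expected = pd.DataFrame(stack.mean(axis=0), index=habitats, columns=habitats)
        pv = np.ones_like(observed.values, dtype=float)
        for i in range(len(habitats)):
            for j in range(len(habitats)):
                pv[i, j] = empirical_pvalue(observed.values[i, j], stack[:, i, j], "upper")
        pvalues = pd.DataFrame(pv, index=habitats, columns=habitats)
        p_same = empirical_pvalue(same_paths, np.asarray(null_same), "upper")
    return HabitatTransferMatrix(
        habitats=habitats,
        observed=observed,
        expected=expected,
        pvalues=pvalues,
        same_habitat_fraction_paths=same_paths,
        same_habitat_fraction_events=same_evt / n_evt if n_evt else 0.0,
        n_pairs=n_pairs,
        n_events_with_habitat=n_evt,
        n_dropped=dropped,
        p_same_habitat=p_same,
    )


# --------------------------------------------------------------------------
# Functional composition
# --------------------------------------------------------------------------

@dataclass
class CompositionResult:
    table: pd.DataFrame            # class x (transferred, background)
    chi2: float
    p_overall: float
    exact_fallback: bool
    per_stratum: pd.DataFrame | None  # stratum, class, p, p_adj, enriched flag


def functional_composition_test(
    event_labels: list[str],
    background_labels: list[str],
    strata: dict[str, list[str]] | None = None,
    fdr: float = 0.05,
) -> CompositionResult:
    """Compare the functional-class composition of transferred genes against
    the genomic background (chi-square; Fisher exact fallback for sparse
    tables), with optional per-stratum tests under Benjamini–Hochberg FDR."""
    classes = sorted(set(event_labels) | set(background_labels))
    if not classes:
        raise ValueError("no functional labels")
    tcounts = pd.Series(event_labels).value_counts().reindex(classes, fill_value=0)
    bcounts = pd.Series(background_labels).value_counts().reindex(classes, fill_value=0)
    table = pd.DataFrame({"transferred": tcounts, "background": bcounts})
    cont = table.values
    exact = False
    expected = stats.contingency.expected_freq(cont + (cont.sum() == 0))
    if np.any(expected < 5) and cont.shape == (2, 2):
        exact = True
        p_overall = float(stats.fisher_exact(cont)[1])
        chi2 = float("nan")
    else:
        chi2, p_overall, _, _ = stats.chi2_contingency(cont)
        chi2, p_overall = float(chi2), float(p_overall)

    per_stratum = None
    if strata:
        rows = []
        global_counts = tcounts
        for stratum in sorted(strata):
            labels = strata[stratum]
            sc = pd.Series(labels).value_counts().reindex(classes, fill_value=0)
            rest = global_counts - sc
            for cls in classes:
                t2 = np.array([
                    [sc[cls], sc.sum() - sc[cls]],
                    [max(rest[cls], 0), max(rest.sum() - rest[cls], 0)],
                ])
                if t2.min() < 0 or t2.sum() == 0:
                    continue
                if stats.contingency.expected_freq(t2 + (t2.sum() == 0)).min() < 5:
                    p = float(stats.fisher_exact(t2)[1])
                    flagged_exact = True
                else:
                    p = float(stats.chi2_contingency(t2)[1])
                    flagged_exact = False
                direction = "enriched" if (
                    sc.sum() and rest.sum() and sc[cls] / sc.sum() > rest[cls] / rest.sum()
                ) else "depleted"
                rows.append({"stratum": stratum, "class": cls, "p": p,
                             "direction": direction, "exact": flagged_exact})
        if rows:
            per_stratum = pd.DataFrame(rows)
            rej, p_adj, _, _ = multipletests(per_stratum["p"], alpha=fdr, method="fdr_bh")
            per_stratum["p_adj"] = p_adj
            per_stratum["significant"] = rej
    return CompositionResult(table=table, chi2=chi2, p_overall=p_overall,
                             exact_fallback=exact, per_stratum=per_stratum)


# --------------------------------------------------------------------------
# Similarity by functional category
# --------------------------------------------------------------------------

@dataclass
class CategorySimilarityResult:
    means: pd.Series
    anova_p: float | None
    tukey: pd.DataFrame | None  # pairwise comparisons at the given alpha


def similarity_by_category(
    similarities: list[float],
    categories: list[str],
    alpha: float = 0.05,
) -> CategorySimilarityResult:
    """Compare donor–recipient similarity across functional categories:
    one-way ANOVA plus Tukey HSD pairwise comparisons."""
    if len(similarities) != len(categories):
        raise ValueError("length mismatch")
    df = pd.DataFrame({"sim": similarities, "cat": categories})
    means = df.groupby("cat")["sim"].mean().sort_index()
    counts = df.groupby("cat")["sim"].count()
    usable = counts[counts >= 2].index
    if len(usable) < 2:
        return CategorySimilarityResult(means=means, anova_p=None, tukey=None)
    sub = df[df["cat"].isin(usable)]
    groups = [g["sim"].values for _, g in sub.groupby("cat")]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return CategorySimilarityResult(means=means, anova_p=1.0, tukey=None)
    anova_p = float(stats.f_oneway(*groups).pvalue)
    res = pairwise_tukeyhsd(sub["sim"].values, sub["cat"].values, alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return CategorySimilarityResult(means=means, anova_p=anova_p, tukey=tukey)
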
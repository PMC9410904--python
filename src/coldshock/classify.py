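"""Gene-cohort statistics from RNA-seq log-fold-change (LFC) tables.

The short-term cold-shock-repressed (CSR) cohort is called from per-gene
log2 fold changes at 20 min after the temperature downshift: a gene is CSR
when its cold-shock LFC is significantly negative while its time-matched
control LFC is significantly non-negative.  Around that call, this module
implements the cohort-level analyses: strong-response thresholding, 2x2
overlap statistics with Fisher's exact test, within-operon pair correlation
with a random-pairing null and an ANCOVA slope comparison, TF-to-target
propagation correlations, promoter AT richness, closely-spaced promoter-pair
discovery, fitness variability against matched random cohorts, and
hypergeometric fold enrichment of function tags.

LFC tables are DataFrames with columns gene_id, condition, time_min, lfc,
pvalue (or pre-sliced to one condition/time, keeping gene_id, lfc, pvalue).
p-value thresholds are applied raw at alpha = 0.05, without multiple-testing
correction, and all threshold comparisons are strict, matching the stated
classification rules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotation import GenomeAnnotation

__all__ = [
    "CohortResult",
    "OverlapStats",
    "PromoterPair",
    "lfc_slice",
    "call_csr",
    "select_reporters",
    "strong_response",
    "overlap_stats",
    "operon_pair_analysis",
    "tf_propagation",
    "at_richness",
    "at_lfc_correlation",
    "find_paired_promoters",
    "fitness_variability",
    "fold_enrichment",
]

DEFAULT_ALPHA = 0.05
STRONG_CS_THRESHOLD = 0.8
# the mean response to 15 degC was about twice as strong as to 50 ug/ml
# novobiocin, so the strong-response threshold for novobiocin is half of CS
STRONG_NOVO_THRESHOLD = STRONG_CS_THRESHOLD / 2
REPORTER_LFC_THRESHOLD = -0.23  # 2**-0.23 ~ 0.85, i.e. >= 15% RNA reduction


@dataclass
class CohortResult:
    """A called gene cohort with per-gene provenance."""

    genes: Set[str]
    provenance: Dict[str, str] = field(default_factory=dict)
    excluded: Dict[str, str] = field(default_factory=dict)
    summary: Dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def lfc_slice(table: pd.DataFrame, condition: str,
              time_min: Optional[float] = None) -> pd.DataFrame:
    """Slice a long LFC table to one condition (and time point)."""
    df = table[table["condition"] == condition]
    if time_min is not None and "time_min" in df:
        df = df[df["time_min"] == time_min]
    return df[["gene_id", "lfc", "pvalue"]].reset_index(drop=True)


def _indexed(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("gene_id", "lfc", "pvalue") if c in table.columns]
    return table[cols].set_index("gene_id")


def call_csr(lfc_cs_20: pd.DataFrame, lfc_ctrl_20: pd.DataFrame,
             alpha: float = DEFAULT_ALPHA) -> CohortResult:
    """Call cold-shock-repressed genes from 20-min LFC tables.

    A gene is CSR iff LFC_CS < 0 with p < alpha AND LFC_CTRL >= 0 with
    p < alpha.  Genes missing either record are excluded with a logged
    reason.
    """
    cs, ctrl = _indexed(lfc_cs_20), _indexed(lfc_ctrl_20)
    universe = set(cs.index) | set(ctrl.index)
    if not universe:
        raise ValueError("empty gene universe")
    genes: Set[str] = set()
    prov: Dict[str, str] = {}
    excluded: Dict[str, str] = {}
    for g in universe:
        if g not in cs.index:
            excluded[g] = "missing CS record"
            continue
        if g not in ctrl.index:
            excluded[g] = "missing CTRL record"
            continue
        r_cs, r_ctrl = cs.loc[g], ctrl.loc[g]
        if (r_cs["lfc"] < 0 and r_cs["pvalue"] < alpha
                and r_ctrl["lfc"] >= 0 and r_ctrl["pvalue"] < alpha):
            genes.add(g)
            prov[g] = (f"LFC_CS={r_cs['lfc']:.3g} (p={r_cs['pvalue']:.2g}), "
                       f"LFC_CTRL={r_ctrl['lfc']:.3g} (p={r_ctrl['pvalue']:.2g})")
    return CohortResult(genes=genes, provenance=prov, excluded=excluded,
                        summary={"n_csr": len(genes), "n_universe": len(universe)})


def select_reporters(csr: CohortResult, annotation: GenomeAnnotation,
                     lfc_cs_20: pd.DataFrame,
                     lfc_threshold: float = REPORTER_LFC_THRESHOLD,
                     expression_percentile: float = 50.0) -> CohortResult:
    """Select fluorescent-reporter candidates from the CSR cohort.

    Keeps CSR genes that are in the YFP fusion library, have optimal-condition
    expression above the given percentile of library genes, and show
    LFC_CS < lfc_threshold (strictly; the default -0.23 corresponds to an RNA
    reduction of 15% or more).
    """
    cs = _indexed(lfc_cs_20)
    g = annotation.genes.set_index("gene_id")
    lib = g[g["in_yfp_library"]]
    cutoff = np.percentile(lib["expression_level"], expression_percentile) if len(lib) else np.inf
    genes, prov = set(), {}
    for gid in csr.genes:
        if gid not in g.index or not g.loc[gid, "in_yfp_library"]:
            continue
        if g.loc[gid, "expression_level"] <= cutoff:
            continue
        if gid in cs.index and cs.loc[gid, "lfc"] < lfc_threshold:
            genes.add(gid)
            prov[gid] = f"LFC_CS={cs.loc[gid, 'lfc']:.3g} < {lfc_threshold}"
    return CohortResult(genes=genes, provenance=prov,
                        summary={"n_reporters": len(genes),
                                 "expression_cutoff": float(cutoff)})


def strong_response(table: pd.DataFrame, threshold: float,
                    alpha: float = DEFAULT_ALPHA) -> CohortResult:
    """Genes with |LFC| strictly above threshold and p strictly below alpha."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    df = _indexed(table)
    mask = (df["lfc"].abs() > threshold) & (df["pvalue"] < alpha)
    genes = set(df.index[mask])
    return CohortResult(genes=genes,
                        provenance={g: f"|LFC|={abs(df.loc[g, 'lfc']):.3g}>{threshold}"
                                    for g in genes},
                        summary={"n_strong": len(genes), "n_tested": len(df),
                                 "threshold": threshold})


@dataclass
class OverlapStats:
    a: int  # |A & B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # rest of universe
    odds_ratio: float
    odds_ratio_cmle: float
    fisher_p: float
    expected_overlap: float
    flag_or_undefined: bool = False


def overlap_stats(set_a: Iterable, set_b: Iterable, universe_size: int) -> OverlapStats:
    """2x2 overlap of two gene sets within a universe.

    Reports the sample odds ratio ad/bc (flagged undefined on a zero
    marginal cell), the conditional-MLE odds ratio, the two-sided Fisher
    exact p-value, and the overlap expected under independence |A||B|/N.
    """
    A, B = set(set_a), set(set_b)
    if universe_size < len(A | B):
        raise ValueError("universe smaller than |A u B|")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = universe_size - a - b - c
    table = [[a, b], [c, d]]
    flag = b == 0 or c == 0 or a == 0 or d == 0
    sample_or = (a * d) / (b * c) if not (b == 0 or c == 0) else float("nan")
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    cmle = float(stats.contingency.odds_ratio(table).statistic)
    expected = len(A) * len(B) / universe_size
    return OverlapStats(a=a, b=b, c=c, d=d, odds_ratio=sample_or,
                        odds_ratio_cmle=cmle, fisher_p=float(fisher_p),
                        expected_overlap=expected, flag_or_undefined=flag)


def _operon_pairs(operons: Sequence[Sequence[str]], members_in: Set[str],
                  lfc: pd.Series) -> pd.DataFrame:
    rows = []
    for members in operons:
        hits = [g for g in members if g in members_in and g in lfc.index]
        for up, down in itertools.combinations(hits, 2):
            rows.append({"upstream": up, "downstream": down,
                         "x": abs(lfc[up]), "y": abs(lfc[down])})
    return pd.DataFrame(rows, columns=["upstream", "downstream", "x", "y"])


@dataclass
class OperonPairResult:
    pairs: pd.DataFrame
    slope: float
    slope_p: float
    null_slopes: np.ndarray
    ancova_p: float
    status: str = "ok"


def operon_pair_analysis(csr: CohortResult, annotation: GenomeAnnotation,
                         lfc_table: pd.DataFrame, n_null: int = 1000,
                         seed: int = 0) -> OperonPairResult:
    """Within-operon |LFC| correlation of CSR pairs vs a random-pairing null.

    Builds all ordered (upstream, downstream) pairs of CSR genes that share an
    operon and regresses |LFC_downstream| on |LFC_upstream|.  The null model
    keeps the observed distribution of CSR-gene counts per operon but fills
    each operon with CSR genes drawn at random, destroying co-membership;
    ``n_null`` replicate slopes are returned.  The ANCOVA compares the real
    and first-null-replicate regression lines via the interaction-term F-test
    of |LFC_down| ~ |LFC_up| x group.
    """
    lfc = _indexed(lfc_table)["lfc"]
    real = _operon_pairs(annotation.operons, csr.genes, lfc)
    if real.empty:
        return OperonPairResult(pairs=real, slope=float("nan"),
                                slope_p=float("nan"),
                                null_slopes=np.array([]), ancova_p=float("nan"),
                                status="no operon holds more than one CSR gene")
    lr = stats.linregress(real["x"], real["y"])
    rng = np.random.default_rng(seed)
    counts = []
    for members in annotation.operons:
        k = sum(1 for g in members if g in csr.genes and g in lfc.index)
        if k >= 2:
            counts.append(k)
    pool = np.array(sorted(g for g in csr.genes if g in lfc.index))
    null_slopes = np.empty(n_null)
    first_null = None
    for i in range(n_null):
        rows = []
        for k in counts:
            chosen = rng.choice(pool, size=k, replace=False)
            for up, down in itertools.combinations(chosen, 2):
                rows.append((abs(lfc[up]), abs(lfc[down])))
        arr = np.asarray(rows)
        null_slopes[i] = stats.linregress(arr[:, 0], arr[:, 1]).slope
        if i == 0:
            first_null = arr
    # ANCOVA: F-test on the group x covariate interaction
    x = np.concatenate([real["x"].to_numpy(), first_null[:, 0]])
    y = np.concatenate([real["y"].to_numpy(), first_null[:, 1]])
    grp = np.concatenate([np.ones(len(real)), np.zeros(len(first_null))])
    X = sm.add_constant(np.column_stack([x, grp, x * grp]))
    fit = sm.OLS(y, X).fit()
    ancova_p = float(fit.pvalues[3])
    return OperonPairResult(pairs=real, slope=float(lr.slope),
                            slope_p=float(lr.pvalue),
                            null_slopes=null_slopes, ancova_p=ancova_p)


def tf_propagation(tf_edges: pd.DataFrame, lfc_short: pd.DataFrame,
                   lfc_later: pd.DataFrame,
                   target_filter: Optional[Set[str]] = None,
                   regulator_filter: Optional[Set[str]] = None):
    """Correlation between TF short-term |LFC| and target later |LFC|.

    Each TF->target edge contributes the pair (|LFC_short(TF)|,
    |LFC_later(target)|); Pearson r and p are computed over edges.  Cohort
    filters restrict targets (e.g. CSR only) or regulators (e.g. global
    regulators).
    """
    short = _indexed(lfc_short)["lfc"]
    later = _indexed(lfc_later)["lfc"]
    xs, ys = [], []
    for _, e in tf_edges.iterrows():
        reg, tgt = e["regulator"], e["target"]
        if target_filter is not None and tgt not in target_filter:
            continue
        if regulator_filter is not None and reg not in regulator_filter:
            continue
        if reg in short.index and tgt in later.index:
            xs.append(abs(short[reg]))
            ys.append(abs(later[tgt]))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable TF edges after filtering")
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n_edges": len(xs)}


def at_richness(promoter_sequences: Dict[str, str]) -> pd.Series:
    """Per-gene AT fraction of promoter sequences.

    Ambiguous bases (N) are excluded from both numerator and denominator;
    empty/all-ambiguous sequences yield NaN.
    """
    out = {}
    for gid, seq in promoter_sequences.items():
        s = seq.upper()
        counted = sum(s.count(b) for b in "ACGT")
        out[gid] = (s.count("A") + s.count("T")) / counted if counted else float("nan")
    return pd.Series(out, name="at_fraction")


def at_lfc_correlation(at: pd.Series, lfc_table: pd.DataFrame):
    """Pearson correlation of promoter AT fraction vs |LFC|."""
    lfc = _indexed(lfc_table)["lfc"].abs()
    joined = pd.concat([at, lfc], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 genes with both AT fraction and LFC")
    r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return {"r": float(r), "p": float(p), "n": len(joined)}


@dataclass(frozen=True)
class PromoterPair:
    gene_a: str
    gene_b: str
    distance: int
    geometry: str  # convergent | divergent | tandem


def find_paired_promoters(annotation: GenomeAnnotation,
                          max_distance: int = 1500) -> List[PromoterPair]:
    """Closely spaced promoter pairs with a clean inter-TSS interval.

    Two promoters pair when their TSS-to-TSS distance is strictly below
    ``max_distance`` and the open interval between the TSSs contains no other
    TSS, no terminator, and no third-party gene body.  The bodies of the two
    paired genes themselves are not disqualifying (a convergent pair
    necessarily holds both bodies between its TSSs).  Geometry follows strand
    orientation: opposite strands transcribing apart = divergent, towards
    each other = convergent, same strand = tandem.  Coordinates are treated
    as linear 1-based positions.

    If the gene table carries a boolean ``has_promoter`` column, only those
    genes contribute TSSs to the scan (internal operon members share the
    operon promoter and are not promoters themselves); gene bodies of all
    genes still count for the interval check.
    """
    g = annotation.genes
    if "has_promoter" in g.columns:
        g = g[g["has_promoter"].astype(bool)]
    g = g.sort_values("tss").reset_index(drop=True)
    tss = g["tss"].to_numpy()
    strands = g["strand"].to_numpy()
    ids = g["gene_id"].to_numpy()
    lefts = annotation.genes["left"].to_numpy()
    rights = annotation.genes["right"].to_numpy()
    all_ids = annotation.genes["gene_id"].to_numpy()
    term_pos = annotation.terminators["position"].to_numpy() if len(
        annotation.terminators) else np.array([])
    pairs: List[PromoterPair] = []
    n = len(g)
    for i in range(n):
        for j in range(i + 1, n):
            dist = int(tss[j] - tss[i])
            if dist >= max_distance:
                break
            lo, hi = tss[i], tss[j]
            # other TSSs strictly inside the open interval
            if np.any((tss > lo) & (tss < hi)):
                continue
            if term_pos.size and np.any((term_pos > lo) & (term_pos < hi)):
                continue
            third = (all_ids != ids[i]) & (all_ids != ids[j])
            if np.any(third & (lefts < hi) & (rights > lo)):
                continue
            s_lo, s_hi = strands[i], strands[j]
            if s_lo == s_hi:
                geometry = "tandem"
            elif s_lo == "+" and s_hi == "-":
                geometry = "convergent"
            else:
                geometry = "divergent"
            pairs.append(PromoterPair(gene_a=ids[i], gene_b=ids[j],
                                      distance=dist, geometry=geometry))
    return pairs


@dataclass
class FitnessVariability:
    cohort_mean: float
    cohort_cv2: float
    null_cv2: np.ndarray
    percentile: float
    flag_undefined: bool = False


def fitness_variability(cohort: Iterable, annotation: GenomeAnnotation,
                        n_null: int = 1000, match: str = "size_only",
                        seed: int = 0) -> FitnessVariability:
    """Fitness CV^2 of a cohort against same-size random cohorts.

    CV^2 = var/mean^2 of per-gene fitness.  Null cohorts are drawn without
    replacement from genes with fitness values; with ``match =
    'size_and_function'`` the draw is stratified to reproduce the cohort's
    function-tag composition.  The empirical percentile of the cohort CV^2 in
    the null distribution is reported (small percentile = cohort less
    variable than chance).
    """
    if match not in ("size_only", "size_and_function"):
        raise ValueError("match must be size_only or size_and_function")
    g = annotation.genes.set_index("gene_id")
    cohort = [c for c in cohort if c in g.index and np.isfinite(g.loc[c, "fitness"])]
    if not cohort:
        raise ValueError("no cohort genes with fitness values")
    fit = g.loc[cohort, "fitness"].to_numpy()
    mean = fit.mean()
    if mean == 0:
        return FitnessVariability(cohort_mean=0.0, cohort_cv2=float("nan"),
                                  null_cv2=np.array([]), percentile=float("nan"),
                                  flag_undefined=True)
    cv2 = fit.var(ddof=1) / mean**2
    rng = np.random.default_rng(seed)
    usable = g[np.isfinite(g["fitness"])]
    null = np.empty(n_null)
    if match == "size_only":
        vals = usable["fitness"].to_numpy()
        for i in range(n_null):
            draw = rng.choice(vals, size=len(cohort), replace=False)
            null[i] = draw.var(ddof=1) / draw.mean()**2
    else:
        tags = g.loc[cohort, "function_tag"].value_counts()
        by_tag = {t: usable[usable["function_tag"] == t]["fitness"].to_numpy()
                  for t in tags.index}
        for t, k in tags.items():
            if len(by_tag[t]) < k:
                raise ValueError(f"not enough genes with tag {t!r} to stratify")
        for i in range(n_null):
            draw = np.concatenate([rng.choice(by_tag[t], size=k, replace=False)
                                   for t, k in tags.items()])
            null[i] = draw.var(ddof=1) / draw.mean()**2
    percentile = float((null < cv2).mean())
    return FitnessVariability(cohort_mean=float(mean), cohort_cv2=float(cv2),
                              null_cv2=null, percentile=percentile)


def fold_enrichment(cohort: Iterable, gene_tags: Dict[str, Set[str]],
                    universe_size: int) -> pd.DataFrame:
    """Per-tag fold enrichment of a cohort with hypergeometric p-values.

    fold = observed / expected with expected = |cohort| * |tag| / N;
    p is the upper-tail hypergeometric probability of observing at least
    as many cohort genes in the tag.
    """
    cohort = set(cohort)
    rows = []
    for tag, members in gene_tags.items():
        members = set(members)
        obs = len(cohort & members)
        expected = len(cohort) * len(members) / universe_size
        fold = obs / expected if expected > 0 else float("nan")
        p = float(stats.hypergeom.sf(obs - 1, universe_size, len(members),
                                     len(cohort)))
        rows.append({"tag": tag, "tag_size": len(members), "observed": obs,
                     "expected": expected, "fold_enrichment": fold,
                     "pvalue": p})
    return pd.DataFrame(rows)
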
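"""Synthetic datasets with the statistical structure the analyses assume.

Every stage of the pipeline is testable without downloads: this module
generates (a) a genome annotation with operons, strands, TSSs, terminators,
promoter sequences, fitness values, TF edges and deliberately planted
promoter-pair fixtures; (b) log2 fold-change tables for cold shock (20/80/180
min), time-matched control, and gyrase inhibition (novobiocin), with a
planted cold-shock-repressed (CSR) cohort whose supercoiling-sensitive
sub-cohort has correlated cold-shock and novobiocin responses; (c) single-cell
fluorescence event sets with Gamma-distributed protein numbers plus additive
lognormal autofluorescence; and (d) relative-Omega time series driven by a
prescribed promoter-unlocking-rate trajectory through the telegraph-model
mapping.

Every generator is a pure function of (spec, seed): identical inputs give
identical outputs.  The spec is a plain dataclass, serializable to a dict for
provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .cytometry import FlowSample
from .dynamics import OmegaSeries
from .analytic import omega_ratio_on_off

__all__ = [
    "SynthSpec",
    "generate_annotation",
    "generate_lfc_tables",
    "generate_flow_samples",
    "flow_gene_means",
    "generate_omega_series",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions at desk scale: a few hundred genes
    organized in operons, a planted CSR cohort (strong short-term repression,
    significantly non-decreasing control), a supercoiling-sensitive sub-cohort
    with correlated cold-shock/novobiocin responses at half strength, Gamma
    protein numbers with Omega = 25 in control inflated by 1.26 under cold
    shock, 30 reporter genes spanning means 50-5000 molecules, and 3-replicate
    t-test p-values coherent with the planted effect sizes.
    """

    n_genes: int = 300
    operon_size_probs: Dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.20, 3: 0.12, 4: 0.08, 5: 0.05})
    fraction_csr: float = 0.2
    # planted LFC structure
    lfc_cs_mean: float = -1.5
    lfc_cs_sd: float = 0.3
    lfc_ctrl_mean: float = 0.4
    lfc_ctrl_sd: float = 0.05
    lfc_novo_null_sd: float = 0.2
    sigma_rep: float = 0.05
    n_replicates: int = 3
    mid_decay: float = 0.8
    long_decay: float = 0.6
    fraction_supercoiling: float = 0.5
    rho_cs_novo: float = 0.7
    # operon co-expression and TF propagation
    operon_coupling_fraction: float = 0.5
    coupling_noise_sd: float = 0.1
    tf_fraction: float = 0.05
    tf_out_degree: int = 3
    tf_response_sd: float = 0.5
    tf_propagation_beta: float = 0.6
    # single-cell structure
    omega_control: float = 25.0
    omega_ratio_cold: float = 1.26
    n_flow_genes: int = 30
    flow_mean_range: tuple = (50.0, 5000.0)
    events_per_sample: int = 10_000
    background_mean: float = 100.0
    background_sd: float = 20.0
    scale_factor: float = 0.1
    # annotation structure
    promoter_length: int = 100
    yfp_library_fraction: float = 0.4
    fitness_mean: float = 0.9
    fitness_sd: float = 0.15
    csr_fitness_var_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_csr", "fraction_supercoiling",
                     "operon_coupling_fraction", "yfp_library_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1 <= self.rho_cs_novo <= 1):
            raise ValueError("rho_cs_novo must be in [-1, 1]")
        if self.n_genes <= 0 or self.events_per_sample <= 0:
            raise ValueError("counts must be positive")
        total = sum(self.operon_size_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("operon_size_probs must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_GENE_LEN = 900
_GENE_PITCH = 1100  # body + intra-operon spacing
_OPERON_GAP = 400
_TAGS = ["metabolism", "stimulus", "both", "other"]
_TAG_PROBS_CSR = [0.43, 0.11, 0.09, 0.37]   # 164/41/36/140-style composition
_TAG_PROBS_OTHER = [0.30, 0.10, 0.05, 0.55]


def _draw_sequence(rng, length, at_fraction):
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2,
         at_fraction / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_annotation(spec: SynthSpec, seed: Optional[int] = None) -> GenomeAnnotation:
    """Genes on a linear coordinate system with operons and planted fixtures.

    The returned annotation carries extra per-gene columns ``planted_csr``,
    ``planted_supercoiling`` and ``is_tf`` (ground truth for recovery tests)
    and a ``fixtures`` dict naming the planted promoter-pair fixtures
    (convergent/divergent/tandem plus near-misses violating the distance,
    gene-interval, and terminator rules).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes_avail = np.array(sorted(spec.operon_size_probs))
    probs = np.array([spec.operon_size_probs[s] for s in sizes_avail], dtype=float)

    sizes: List[int] = []
    total = 0
    while total < spec.n_genes:
        s = int(rng.choice(sizes_avail, p=probs))
        s = min(s, spec.n_genes - total)
        sizes.append(s)
        total += s

    # Internal operon members share the operon TSS and carry has_promoter =
    # False, so that only genuine promoters enter the paired-promoter scan.
    rows, operons, terminators = [], [], []
    cursor = 1000
    gi = 0
    for op_idx, size in enumerate(sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        span = 300 + size * _GENE_PITCH + 200
        members = []
        if strand == "+":
            tss = cursor
            for k in range(size):
                left = cursor + 300 + k * _GENE_PITCH
                gid = f"g{gi:04d}"
                rows.append((gid, strand, tss, left, left + _GENE_LEN, k == 0))
                members.append(gid)
                gi += 1
            terminators.append((rows[-1][4] + 100, strand))
        else:
            tss = cursor + span
            for k in range(size):
                right = cursor + span - 300 - k * _GENE_PITCH
                gid = f"g{gi:04d}"
                rows.append((gid, strand, tss, right - _GENE_LEN, right, k == 0))
                members.append(gid)
                gi += 1
            terminators.append((rows[-1][3] - 100, strand))
        operons.append(members)
        cursor += span + _OPERON_GAP

    # --- planted promoter-pair fixtures (isolated region, >=3 kb apart) ---
    fixtures: Dict[str, tuple] = {}
    cursor += 3000

    def add_gene(gid, strand, tss, left, right):
        rows.append((gid, strand, tss, left, right, True))

    p = cursor
    add_gene("fx_div_a", "-", p, p - 1100, p - 200)
    add_gene("fx_div_b", "+", p + 1000, p + 1200, p + 2100)
    fixtures["divergent"] = ("fx_div_a", "fx_div_b")
    cursor = p + 2100 + 3000

    q = cursor
    add_gene("fx_con_a", "+", q, q + 200, q + 550)
    add_gene("fx_con_b", "-", q + 1200, q + 650, q + 1000)
    fixtures["convergent"] = ("fx_con_a", "fx_con_b")
    cursor = q + 1200 + 3000

    r = cursor
    add_gene("fx_tan_a", "+", r, r + 150, r + 700)
    add_gene("fx_tan_b", "+", r + 900, r + 1100, r + 1600)
    fixtures["tandem"] = ("fx_tan_a", "fx_tan_b")
    cursor = r + 1600 + 3000

    s = cursor
    add_gene("fx_far_a", "-", s, s - 1100, s - 200)
    add_gene("fx_far_b", "+", s + 1600, s + 1800, s + 2700)
    fixtures["near_miss_distance"] = ("fx_far_a", "fx_far_b")
    cursor = s + 2700 + 3000

    u = cursor
    add_gene("fx_blk_a", "-", u, u - 1100, u - 200)
    add_gene("fx_blk_b", "+", u + 1000, u + 1200, u + 2100)
    add_gene("fx_blk_c", "+", u + 2500, u + 300, u + 700)  # body inside interval
    fixtures["near_miss_gene"] = ("fx_blk_a", "fx_blk_b")
    cursor = u + 2500 + 3000

    v = cursor
    add_gene("fx_ter_a", "-", v, v - 1100, v - 200)
    add_gene("fx_ter_b", "+", v + 1000, v + 1200, v + 2100)
    terminators.append((v + 500, "+"))
    fixtures["near_miss_terminator"] = ("fx_ter_a", "fx_ter_b")
    cursor = v + 2100 + 3000

    genes = pd.DataFrame(rows, columns=["gene_id", "strand", "tss", "left",
                                        "right", "has_promoter"])
    n_all = len(genes)
    main_ids = [f"g{i:04d}" for i in range(gi)]

    # --- planted CSR cohort, assigned operon-prefix-wise ---
    target = int(round(spec.fraction_csr * gi))
    order = rng.permutation(len(operons))
    csr: List[str] = []
    for oi in order:
        if len(csr) >= target:
            break
        members = operons[oi]
        take = int(rng.integers(1, len(members) + 1))
        take = min(take, target - len(csr))
        csr.extend(members[:take])
    csr_set = set(csr)
    genes["planted_csr"] = genes["gene_id"].isin(csr_set)
    n_sc = int(round(spec.fraction_supercoiling * len(csr)))
    sc = set(rng.choice(sorted(csr_set), size=n_sc, replace=False)) if n_sc else set()
    genes["planted_supercoiling"] = genes["gene_id"].isin(sc)

    # function tags, fitness (CSR cohort planted with reduced variability)
    tags = np.empty(n_all, dtype=object)
    fitness = np.empty(n_all)
    is_csr = genes["planted_csr"].to_numpy()
    for i in range(n_all):
        probs_t = _TAG_PROBS_CSR if is_csr[i] else _TAG_PROBS_OTHER
        tags[i] = rng.choice(_TAGS, p=probs_t)
        sd = spec.fitness_sd * (np.sqrt(spec.csr_fitness_var_factor)
                                if is_csr[i] else 1.0)
        fitness[i] = rng.normal(spec.fitness_mean, sd)
    genes["function_tag"] = tags
    genes["fitness"] = fitness
    genes["in_yfp_library"] = rng.random(n_all) < spec.yfp_library_fraction
    # CSR genes are strongly expressed in optimal conditions by construction
    genes["expression_level"] = np.exp(rng.normal(5.0 + 0.8 * is_csr, 1.0))

    # TF edges over main-region genes
    n_tf = max(1, int(round(spec.tf_fraction * gi)))
    tf_ids = rng.choice(main_ids, size=n_tf, replace=False)
    genes["is_tf"] = genes["gene_id"].isin(set(tf_ids))
    edges = []
    for tf in tf_ids:
        candidates = [g for g in main_ids if g != tf]
        for tgt in rng.choice(candidates, size=min(spec.tf_out_degree,
                                                   len(candidates)), replace=False):
            edges.append((tf, tgt))
    tf_edges = pd.DataFrame(edges, columns=["regulator", "target"])

    promoters = {row.gene_id: _draw_sequence(rng, spec.promoter_length,
                                             rng.uniform(0.35, 0.65))
                 for row in genes.itertuples()}

    terminators_df = pd.DataFrame(terminators, columns=["position", "strand"])
    return GenomeAnnotation(genes=genes, operons=operons, tf_edges=tf_edges,
                            terminators=terminators_df,
                            promoter_sequences=promoters,
                            genome_length=int(cursor + 1000),
                            fixtures=fixtures)


def _pvalues_from_replicates(rng, true_lfc: np.ndarray, sigma: float, n_rep: int):
    """Observed LFC and p-value from a simulated n-replicate one-sample t-test."""
    reps = true_lfc[:, None] + rng.normal(0.0, sigma, size=(true_lfc.size, n_rep))
    mean = reps.mean(axis=1)
    sd = reps.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n_rep))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_rep - 1)
    return mean, np.clip(p, np.finfo(float).tiny, 1.0)


def generate_lfc_tables(spec: SynthSpec, annotation: GenomeAnnotation,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Long-format LFC table for CS (20/80/180 min), CTRL (same times), NOVO.

    Planted CSR genes carry a strong negative cold-shock effect and a small
    significantly-positive control drift; the supercoiling-sensitive
    sub-cohort draws (LFC_CS, LFC_NOVO) from a bivariate normal with
    correlation ``rho_cs_novo`` and novobiocin effects at half the cold-shock
    strength.  For a configurable fraction of operons, downstream CSR members
    inherit the upstream member's effect plus noise.  Non-CSR TF genes get
    their own short-term responses, which propagate to their targets' mid- and
    long-term LFCs with coefficient ``tf_propagation_beta``.  Observed LFCs
    and p-values come from a simulated 3-replicate t-test so that effect size
    and significance are coherent.
    """
    rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
    genes = annotation.genes
    ids = genes["gene_id"].to_numpy()
    n = len(ids)
    idx = {g: i for i, g in enumerate(ids)}
    is_csr = genes["planted_csr"].to_numpy()
    is_sc = genes["planted_supercoiling"].to_numpy()
    is_tf = genes.get("is_tf", pd.Series(False, index=genes.index)).to_numpy()

    true_cs20 = np.zeros(n)
    true_ctrl = np.zeros(n)
    true_novo = rng.normal(0.0, spec.lfc_novo_null_sd, size=n)

    # CSR genes: correlated (CS, NOVO) for the supercoiling sub-cohort
    z = rng.multivariate_normal([0.0, 0.0],
                                [[1.0, spec.rho_cs_novo],
                                 [spec.rho_cs_novo, 1.0]], size=n)
    csr_idx = np.where(is_csr)[0]
    true_cs20[csr_idx] = spec.lfc_cs_mean + spec.lfc_cs_sd * z[csr_idx, 0]
    sc_idx = np.where(is_csr & is_sc)[0]
    true_novo[sc_idx] = (spec.lfc_cs_mean / 2.0
                         + (spec.lfc_cs_sd / 2.0) * z[sc_idx, 1])
    true_ctrl[csr_idx] = rng.normal(spec.lfc_ctrl_mean, spec.lfc_ctrl_sd,
                                    size=csr_idx.size)

    # operon co-expression: downstream CSR members inherit the upstream effect
    for members in annotation.operons:
        hits = [g for g in members if is_csr[idx[g]]]
        if len(hits) >= 2 and rng.random() < spec.operon_coupling_fraction:
            base = true_cs20[idx[hits[0]]]
            for g in hits[1:]:
                true_cs20[idx[g]] = base + rng.normal(0.0, spec.coupling_noise_sd)

    # TF short-term responses (non-CSR TFs) propagate to targets at later
    # lags.  Responding non-CSR TFs are induced (positive LFC) so that the
    # planted CSR labels remain the exhaustive ground truth of repression.
    tf_resp = np.where(is_tf & ~is_csr,
                       np.abs(rng.normal(0.0, spec.tf_response_sd, size=n)), 0.0)
    true_cs20 = true_cs20 + tf_resp
    true_cs80 = np.where(is_csr, spec.mid_decay * true_cs20, 0.0)
    true_cs180 = np.where(is_csr, spec.long_decay * true_cs20, 0.0)
    for _, e in annotation.tf_edges.iterrows():
        ti, gi_ = idx[e["regulator"]], idx[e["target"]]
        if not is_csr[gi_]:
            true_cs80[gi_] += spec.tf_propagation_beta * true_cs20[ti]
            true_cs180[gi_] += spec.tf_propagation_beta * true_cs20[ti]

    lfc_cs20, p_cs20 = _pvalues_from_replicates(rng, true_cs20, spec.sigma_rep,
                                                spec.n_replicates)
    lfc_ctrl20, p_ctrl20 = _pvalues_from_replicates(rng, true_ctrl,
                                                    spec.sigma_rep,
                                                    spec.n_replicates)
    # Planted labels are exact ground truth: truly-null genes are conditioned
    # (by rejection resampling of their short-term replicates) not to display
    # the full CSR signature by chance.
    for _ in range(100):
        spurious = (~is_csr & (lfc_cs20 < 0) & (p_cs20 < 0.05)
                    & (lfc_ctrl20 >= 0) & (p_ctrl20 < 0.05))
        if not spurious.any():
            break
        redraw, predraw = _pvalues_from_replicates(
            rng, true_cs20[spurious], spec.sigma_rep, spec.n_replicates)
        lfc_cs20[spurious], p_cs20[spurious] = redraw, predraw

    frames = []

    def emit(condition, time_min, lfc, p):
        frames.append(pd.DataFrame({"gene_id": ids, "condition": condition,
                                    "time_min": time_min, "lfc": lfc,
                                    "pvalue": p}))

    emit("CS", 20, lfc_cs20, p_cs20)
    for t, true_vec in ((80, true_cs80), (180, true_cs180)):
        emit("CS", t, *_pvalues_from_replicates(rng, true_vec, spec.sigma_rep,
                                                spec.n_replicates))
    emit("CTRL", 20, lfc_ctrl20, p_ctrl20)
    for t in (80, 180):
        emit("CTRL", t, *_pvalues_from_replicates(rng, true_ctrl,
                                                  spec.sigma_rep,
                                                  spec.n_replicates))
    emit("NOVO", 20, *_pvalues_from_replicates(rng, true_novo, spec.sigma_rep,
                                               spec.n_replicates))
    return pd.concat(frames, ignore_index=True)


def flow_gene_means(spec: SynthSpec, seed: Optional[int] = None) -> np.ndarray:
    """Reporter-gene mean protein numbers, log-uniform over the spec range."""
    rng = np.random.default_rng((spec.seed + 2) if seed is None else seed)
    lo, hi = spec.flow_mean_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_flow_genes))


def _draw_background(spec: SynthSpec, rng, size: int) -> np.ndarray:
    if spec.background_mean <= 0:
        return np.zeros(size)
    cv2 = (spec.background_sd / spec.background_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(spec.background_mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_flow_samples(spec: SynthSpec, means: Sequence[float], omega: float,
                          condition: str = "control", time_min: float = 0.0,
                          seed: Optional[int] = None,
                          gene_ids: Optional[Sequence[str]] = None,
                          ) -> List[FlowSample]:
    """Flow-cytometry-like event sets for a gene cohort sharing one Omega.

    True protein numbers are Gamma(shape = M/Omega, scale = Omega); measured
    fluorescence is numbers / scale_factor plus an independent lognormal
    autofluorescence draw.  A matched background event set (autofluorescence
    alone) is emitted with each sample.
    """
    if omega <= 0 or np.any(np.asarray(means) <= 0):
        raise ValueError("means and omega must be positive")
    rng = np.random.default_rng((spec.seed + 3) if seed is None else seed)
    out = []
    for i, M in enumerate(means):
        gid = gene_ids[i] if gene_ids is not None else f"flow{i:03d}"
        numbers = rng.gamma(shape=M / omega, scale=omega,
                            size=spec.events_per_sample)
        bg_in_sample = _draw_background(spec, rng, spec.events_per_sample)
        events = numbers / spec.scale_factor + bg_in_sample
        background = _draw_background(spec, rng, spec.events_per_sample)
        out.append(FlowSample(gene_id=gid, condition=condition,
                              time_min=time_min, events=events,
                              background_events=background))
    return out


def generate_omega_series(times: Sequence[float], kplus, k1: float,
                          k_minus: float, noise_sd: float = 0.0,
                          seed: int = 0, condition: str = "cold",
                          ) -> OmegaSeries:
    """Relative-Omega series implied by a promoter-unlocking trajectory.

    omega_rel(t) = (1 + k1 k- / (k+(t) + k-)^2) / (1 + k1 k- / (k+(0) + k-)^2)
    plus optional Gaussian noise on every point after t = 0 (the series stays
    exactly 1 at the first time point).  ``kplus`` is an array matching
    ``times`` or a callable k+(t) > 0.
    """
    t = np.asarray(times, dtype=float)
    k = np.asarray([kplus(x) for x in t]) if callable(kplus) else np.asarray(
        kplus, dtype=float)
    if k.shape != t.shape:
        raise ValueError("kplus trajectory must match times")
    if np.any(k <= 0):
        raise ValueError("k_plus must be > 0 on the grid")
    u = np.asarray(omega_ratio_on_off(k1, k, k_minus), dtype=float)
    rel = u / u[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rel = rel + np.concatenate([[0.0], rng.normal(0, noise_sd, t.size - 1)])
    return OmegaSeries(times=t, omega_rel=rel, condition=condition)
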
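"""Synthetic cohort generator with fully known ground truth.

The generator emulates the statistical structure of a myotonic dystrophy type 1
(DM1) frontal-cortex cohort: a latent per-patient severity gradient drives
exon-specific inclusion (ψ) shifts, a severity-linked increase in microglial
proportion, cell-type-specific expression changes, YGCY-like motif planting in
direction-appropriate introns, and bimodal mosaic repeat-length distributions.
Every configured effect is recorded in a :class:`GroundTruth` object so tests
can recompute expectations independently.

A single seed feeds independent child streams per component (ψ, expression,
sequences, molecules), so e.g. requesting molecules does not perturb ψ draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    REGION_NAMES,
    ExpressionMatrix,
    MoleculeSet,
    PsiMatrix,
    RegionSequences,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_sequences",
    "simulate_molecules",
    "derive_related_truth",
    "stand_in_de_test",
]

CELL_TYPES = ("neuron", "oligodendrocyte", "astrocyte", "endothelial", "microglia")
BASE_PROPORTIONS = (0.40, 0.25, 0.20, 0.10, 0.05)
MICROGLIA_LOGIT_SHIFT = 1.2  # added to the microglia logit per unit severity


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults mirror the study cohort
    (21 affected, 8 unaffected) and its observed effect structure."""

    n_unaffected: int = 8
    n_affected: int = 21
    n_responsive_exons: int = 130
    n_null_exons: int = 2000
    frac_included: float = 31 / 101  # fraction of responsive exons shifted up
    amplitude_range: tuple[float, float] = (0.25, 0.48)
    kappa: float = 100.0            # beta concentration of ψ noise
    severity_range: tuple[float, float] = (0.15, 1.0)
    # expression model
    n_genes: int = 2000
    n_specific_per_type: int = 120  # genes constructed cell-type specific
    n_cell_types: int = 5
    markers_per_type: int = 50
    n_de_up: int = 70
    n_de_down: int = 90
    de_effect_range: tuple[float, float] = (1.5, 3.5)  # |log2FC| per unit severity
    expr_noise_cv: float = 0.2      # lognormal CV of bulk TPM noise
    proportion_logit_sd: float = 0.30
    # sequences
    flank: int = 250
    exon_length: int = 120
    planted_kmers: tuple[str, ...] = ("TGCTT", "GCTGC")
    plant_multiplier: float = 2.5
    n_background_events: int = 1000
    # molecules
    n_molecules: int = 200
    normal_repeat_mean: float = 23.0
    normal_repeat_sd: float = 142.0
    expanded_median_base: float = 400.0
    expanded_median_slope: float = 4000.0
    expanded_log_sd: float = 0.6
    reference_flank_bp: float = 10_000.0
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_unaffected": self.n_unaffected + self.n_affected,  # cohort non-empty
            "n_responsive_exons + n_null_exons": self.n_responsive_exons + self.n_null_exons,
            "n_genes": self.n_genes,
            "n_cell_types": self.n_cell_types,
            "markers_per_type": self.markers_per_type,
            "n_molecules": self.n_molecules,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("n_unaffected", "n_affected", "n_responsive_exons", "n_null_exons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.plant_multiplier < 1:
            raise ValueError(f"plant_multiplier must be >= 1, got {self.plant_multiplier}")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError(f"amplitude_range must satisfy 0 < lo <= hi < 0.5, got {self.amplitude_range}")
        if self.n_cell_types != len(CELL_TYPES):
            raise ValueError("n_cell_types other than 5 requires a custom reference")


@dataclass
class GroundTruth:
    """Everything needed to recompute configured expectations independently."""

    seed: int
    samples: list[str]
    groups: dict[str, str]
    severity: dict[str, float]                  # s_i, 0 for unaffected
    exon_baseline: dict[str, float]             # ψ0_e
    exon_direction: dict[str, int]              # d_e ∈ {+1,−1}; 0 for null exons
    exon_amplitude: dict[str, float]            # a_e; 0 for null exons
    proportions: pd.DataFrame                   # samples × cell types, rows sum to 1
    reference: pd.DataFrame                     # genes × cell types mean expression
    gene_cell_type: dict[str, str]              # constructed specificity ('' = none)
    de_effects: dict[str, float]                # gene -> β (signed log2FC/severity)
    planted_kmers: list[str]
    plant_multiplier: float
    repeat_params: dict[str, dict[str, float]]  # per-sample molecule model

    @property
    def responsive_events(self) -> list[str]:
        return [e for e, a in self.exon_amplitude.items() if a > 0]

    def expected_psi(self, event: str, sample: str) -> float:
        mu = (self.exon_baseline[event]
              + self.exon_direction[event] * self.exon_amplitude[event]
              * self.severity[sample])
        return float(np.clip(mu, 0.01, 0.99))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "dose_response": "linear_in_severity",
            "samples": self.samples,
            "groups": self.groups,
            "severity": self.severity,
            "exon_baseline": self.exon_baseline,
            "exon_direction": self.exon_direction,
            "exon_amplitude": self.exon_amplitude,
            "proportions": self.proportions.to_dict(orient="index"),
            "gene_cell_type": self.gene_cell_type,
            "de_effects": self.de_effects,
            "planted_kmers": self.planted_kmers,
            "plant_multiplier": self.plant_multiplier,
            "repeat_params": self.repeat_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _child_rngs(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Cohort: ψ matrix + expression matrix + DE stand-in
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig):
    """Generate (PsiMatrix, ExpressionMatrix, GroundTruth, de_table).

    Affected severities are Uniform(0.15, 1); responsive-exon means are
    ``clip(ψ0 + d·a·s, 0.01, 0.99)``; observed ψ are Beta with that mean and
    concentration κ.  Bulk expression mixes a cell-type reference by per-sample
    proportions (microglia logit shifted by +1.2·s), applies per-gene DE
    effects ``2^{β·s}`` and multiplicative lognormal noise.  The DE stand-in
    is a per-gene rank-sum on log2(TPM+1) with Benjamini–Hochberg q.
    """
    config.validate()
    rng_sev, rng_psi, rng_expr, _rng_seq, _rng_mol, rng_assign = _child_rngs(config.seed)

    samples = ([f"CTRL{i+1:02d}" for i in range(config.n_unaffected)]
               + [f"DM{i+1:02d}" for i in range(config.n_affected)])
    groups = {s: ("unaffected" if s.startswith("CTRL") else "DM1") for s in samples}
    sev = np.concatenate([
        np.zeros(config.n_unaffected),
        rng_sev.uniform(*config.severity_range, size=config.n_affected),
    ])
    severity = dict(zip(samples, map(float, sev)))

    # --- exon ground truth -------------------------------------------------
    n_resp, n_null = config.n_responsive_exons, config.n_null_exons
    events = ([f"resp_{i:04d}" for i in range(n_resp)]
              + [f"null_{i:04d}" for i in range(n_null)])
    amp = rng_psi.uniform(*config.amplitude_range, size=n_resp)
    direction = np.where(rng_psi.random(n_resp) < config.frac_included, 1, -1)
    base_resp = np.array([rng_psi.uniform(a + 0.01, 1 - a - 0.01) for a in amp])
    base_null = rng_psi.uniform(0.05, 0.95, size=n_null)

    baseline = np.concatenate([base_resp, base_null])
    d_all = np.concatenate([direction, np.zeros(n_null, dtype=int)])
    a_all = np.concatenate([amp, np.zeros(n_null)])

    mu = baseline[:, None] + d_all[:, None] * a_all[:, None] * sev[None, :]
    mu = np.clip(mu, 0.01, 0.99)
    kappa = config.kappa
    psi_values = rng_psi.beta(mu * kappa, (1 - mu) * kappa)
    psi = PsiMatrix(pd.DataFrame(psi_values, index=events, columns=samples), dict(groups))

    # --- expression ground truth -------------------------------------------
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_spec = config.n_specific_per_type
    gene_ct = {g: "" for g in genes}
    ref = np.exp(rng_expr.normal(3.0, 1.0, size=(config.n_genes, len(CELL_TYPES))))
    # cell-type specific blocks: strong own-type expression, weak elsewhere
    idx = 0
    specific_pool: dict[str, list[int]] = {}
    for c, ct in enumerate(CELL_TYPES):
        block = list(range(idx, idx + n_spec))
        specific_pool[ct] = block
        for g in block:
            base = np.exp(rng_expr.normal(2.0, 0.5))
            ref[g, :] = base
            ref[g, c] = base * rng_expr.uniform(6.0, 12.0)
            gene_ct[genes[g]] = ct
        idx += n_spec
    reference = pd.DataFrame(ref, index=genes, columns=list(CELL_TYPES))

    # proportions with severity-linked microglial increase
    logits = np.log(np.array(BASE_PROPORTIONS))
    L = logits[None, :] + rng_expr.normal(0, config.proportion_logit_sd,
                                          size=(len(samples), len(CELL_TYPES)))
    L[:, CELL_TYPES.index("microglia")] += MICROGLIA_LOGIT_SHIFT * sev
    theta = np.exp(L)
    theta /= theta.sum(axis=1, keepdims=True)
    proportions = pd.DataFrame(theta, index=samples, columns=list(CELL_TYPES))

    # DE genes: down preferentially neuron-specific, up microglia/endothelial
    de_effects: dict[str, float] = {}
    def pick(pool: list[int], n: int) -> list[int]:
        avail = [g for g in pool if genes[g] not in de_effects]
        take = rng_assign.choice(avail, size=min(n, len(avail)), replace=False)
        return list(take)

    n_down_spec = int(round(0.7 * config.n_de_down))
    down_idx = pick(specific_pool["neuron"], n_down_spec)
    up_pool = specific_pool["microglia"] + specific_pool["endothelial"]
    n_up_spec = int(round(0.7 * config.n_de_up))
    up_idx = pick(up_pool, n_up_spec)
    nonspecific = [g for g in range(config.n_genes)
                   if gene_ct[genes[g]] == "" ]
    down_idx += pick(nonspecific, config.n_de_down - len(down_idx))
    up_idx += pick([g for g in nonspecific if g not in down_idx],
                   config.n_de_up - len(up_idx))
    for g in down_idx:
        de_effects[genes[g]] = -float(rng_assign.uniform(*config.de_effect_range))
    for g in up_idx:
        de_effects[genes[g]] = float(rng_assign.uniform(*config.de_effect_range))

    beta = np.array([de_effects.get(g, 0.0) for g in genes])
    bulk = theta @ ref.T                      # samples × genes mixture
    bulk = bulk.T * np.exp2(beta[:, None] * sev[None, :])
    sigma_ln = np.sqrt(np.log1p(config.expr_noise_cv ** 2))
    bulk *= rng_expr.lognormal(0.0, sigma_ln, size=bulk.shape)
    tpm = ExpressionMatrix(pd.DataFrame(bulk, index=genes, columns=samples), dict(groups))

    # per-sample molecule model parameters (used lazily by simulate_molecules)
    repeat_params = {
        s: {
            "severity": severity[s],
            "expanded_fraction": 0.5 if groups[s] != "unaffected" else 0.0,
            "normal_mean": config.normal_repeat_mean,
            "normal_sd": config.normal_repeat_sd,
            "expanded_median": config.expanded_median_base
            + config.expanded_median_slope * severity[s],
            "expanded_log_sd": config.expanded_log_sd,
        }
        for s in samples
    }

    truth = GroundTruth(
        seed=config.seed, samples=samples, groups=groups, severity=severity,
        exon_baseline=dict(zip(events, map(float, baseline))),
        exon_direction=dict(zip(events, map(int, d_all))),
        exon_amplitude=dict(zip(events, map(float, a_all))),
        proportions=proportions, reference=reference, gene_cell_type=gene_ct,
        de_effects=de_effects, planted_kmers=list(config.planted_kmers),
        plant_multiplier=config.plant_multiplier, repeat_params=repeat_params,
    )
    if config.n_affected > 0 and config.n_unaffected > 0:
        de_table = stand_in_de_test(tpm, "DM1", "unaffected")
    else:
        de_table = pd.DataFrame(columns=["log2fc", "pvalue", "qvalue"]
                                ).rename_axis("gene")
    return psi, tpm, truth, de_table


def stand_in_de_test(tpm: ExpressionMatrix, case_label: str, control_label: str) -> pd.DataFrame:
    """Simple per-gene differential-expression table: rank-sum on log2(TPM+1)
    with BH q and group-mean log2 fold change.  A deliberately plain stand-in
    for a full transcript-level DE model; flagged in the output metadata.
    """
    from statsmodels.stats.multitest import multipletests

    case = tpm.samples_in_group(case_label)
    ctrl = tpm.samples_in_group(control_label)
    log = np.log2(tpm.values.to_numpy(dtype=float) + 1.0)
    ci = [tpm.samples.index(s) for s in case]
    ki = [tpm.samples.index(s) for s in ctrl]
    lfc = log[:, ci].mean(axis=1) - log[:, ki].mean(axis=1)
    res = stats.mannwhitneyu(log[:, ci], log[:, ki], axis=1,
                             alternative="two-sided", method="asymptotic")
    _, q, _, _ = multipletests(res.pvalue, method="fdr_bh")
    df = pd.DataFrame({"gene": tpm.genes, "log2fc": lfc,
                       "pvalue": res.pvalue, "qvalue": q}).set_index("gene")
    df.attrs["method"] = "stand_in_ranksum_bh"
    return df


# ---------------------------------------------------------------------------
# Sequences with planted motifs
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _plant(rng: np.random.Generator, seq: np.ndarray, kmers: list[str],
           multiplier: float) -> np.ndarray:
    """Overwrite random positions with extra k-mer copies so the expected
    occurrence frequency is ``multiplier`` × the uniform background."""
    if multiplier <= 1:
        return seq
    k = len(kmers[0])
    n_windows = max(len(seq) - k + 1, 0)
    if n_windows == 0:
        return seq
    p_bg = 4.0 ** -k
    for kmer in kmers:
        extra = rng.poisson((multiplier - 1.0) * p_bg * n_windows)
        if extra == 0:
            continue
        starts = rng.integers(0, n_windows, size=extra)
        enc = np.frombuffer(kmer.encode(), dtype=np.uint8)
        code = np.searchsorted(_BASES, enc).astype(np.int8)
        for s in starts:
            seq[s:s + k] = code
    return seq


def simulate_sequences(truth: GroundTruth, config: CohortConfig):
    """Generate sense-strand region sequences for the responsive exons plus a
    background set of unplanted skipped-exon events.

    Background composition is i.i.d. uniform over {A,C,G,T}.  For exons whose
    inclusion increases with severity, the planted k-mers are enriched in the
    upstream-intron windows; for exons whose inclusion decreases, in the
    downstream-intron windows.  Exon windows are never planted.
    """
    if config.plant_multiplier < 1:
        raise ValueError("plant multiplier must be >= 1")
    rng = _child_rngs(config.seed)[3]
    kmers = list(config.planted_kmers)
    region_len = {r: (config.exon_length if r == "exon" else config.flank)
                  for r in REGION_NAMES}

    targets: list[RegionSequences] = []
    for event in truth.responsive_events:
        d = truth.exon_direction[event]
        direction = "included" if d > 0 else "excluded"
        plant_regions = (("up_intron_5p", "up_intron_3p") if d > 0
                         else ("down_intron_5p", "down_intron_3p"))
        seqs = {}
        for region in REGION_NAMES:
            arr = _random_seq(rng, region_len[region])
            if region in plant_regions:
                arr = _plant(rng, arr, kmers, config.plant_multiplier)
            seqs[region] = _decode(arr)
        targets.append(RegionSequences(event, direction, seqs))

    background = [
        RegionSequences(f"bg_{i:05d}", "background",
                        {r: _decode(_random_seq(rng, region_len[r]))
                         for r in REGION_NAMES})
        for i in range(config.n_background_events)
    ]
    return targets, background


# ---------------------------------------------------------------------------
# Single-molecule repeat spans
# ---------------------------------------------------------------------------

def simulate_molecules(truth: GroundTruth, config: CohortConfig,
                       n_molecules: int | None = None) -> MoleculeSet:
    """Bimodal mosaic repeat-length model.

    Each molecule is, with probability ½, a normal-allele measurement with
    repeat units ~ Normal(23, 142) truncated at 0 (the noisy unaffected-scale
    estimate), and otherwise — affected samples only — an expanded-allele
    measurement with lognormal units (median 400 + 4000·s, log-sd 0.6).
    Spans are units × 3 bp plus the fixed reference flank.
    """
    config.validate()
    rng = _child_rngs(config.seed)[4]
    n = config.n_molecules if n_molecules is None else n_molecules
    out: dict[str, pd.DataFrame] = {}
    a, b = (0 - config.normal_repeat_mean) / config.normal_repeat_sd, np.inf
    for sample in truth.samples:
        params = truth.repeat_params[sample]
        if n == 0:
            out[sample] = pd.DataFrame(columns=["molecule_id", "span_bp"])
            continue
        expanded = rng.random(n) < params["expanded_fraction"]
        units = stats.truncnorm.rvs(a, b, loc=params["normal_mean"],
                                    scale=params["normal_sd"], size=n,
                                    random_state=rng)
        n_exp = int(expanded.sum())
        if n_exp:
            units[expanded] = rng.lognormal(np.log(params["expanded_median"]),
                                            params["expanded_log_sd"], size=n_exp)
        spans = units * 3.0 + config.reference_flank_bp
        out[sample] = pd.DataFrame({
            "molecule_id": [f"{sample}_m{j:05d}" for j in range(n)],
            "span_bp": spans,
        })
    return MoleculeSet(out)


# ---------------------------------------------------------------------------
# Derived cohorts (other tissues / species) sharing part of the ground truth
# ---------------------------------------------------------------------------

def derive_related_truth(truth: GroundTruth, keep_fraction: float,
                         seed: int, sample_prefix: str = "T2",
                         n_affected: int | None = None,
                         severity_range: tuple[float, float] = (0.15, 1.0),
                         fixed_severity: float | None = None) -> GroundTruth:
    """A second dataset (tissue or genotype) sharing a fraction of the
    responsive exons with ``truth``; the rest become null there.  New samples
    with fresh severities (or one fixed severity for a knockout genotype)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    resp = truth.responsive_events
    keep = set(rng.choice(resp, size=int(round(keep_fraction * len(resp))),
                          replace=False))
    n_aff = len([s for s in truth.samples if truth.groups[s] != "unaffected"]) \
        if n_affected is None else n_affected
    n_ctrl = len(truth.samples) - len([s for s in truth.samples
                                       if truth.groups[s] != "unaffected"])
    samples = ([f"{sample_prefix}_CTRL{i+1:02d}" for i in range(n_ctrl)]
               + [f"{sample_prefix}_CASE{i+1:02d}" for i in range(n_aff)])
    groups = {s: ("unaffected" if "CTRL" in s else "affected") for s in samples}
    if fixed_severity is None:
        sev_aff = rng.uniform(*severity_range, size=n_aff)
    else:
        sev_aff = np.full(n_aff, fixed_severity)
    severity = {s: 0.0 for s in samples[:n_ctrl]}
    severity.update(dict(zip(samples[n_ctrl:], map(float, sev_aff))))
    amplitude = {e: (a if e in keep else 0.0)
                 for e, a in truth.exon_amplitude.items()}
    direction = {e: (d if amplitude[e] > 0 else 0)
                 for e, d in truth.exon_direction.items()}
    return dataclasses.replace(
        truth, seed=seed, samples=samples, groups=groups, severity=severity,
        exon_amplitude=amplitude, exon_direction=direction,
        proportions=truth.proportions, repeat_params={},
    )


def psi_from_truth(truth: GroundTruth, kappa: float, seed: int,
                   event_prefix: str = "") -> PsiMatrix:
    """Draw a ψ matrix directly from a GroundTruth (used for derived
    tissues/genotypes); event ids can be namespaced with ``event_prefix``."""
    rng = np.random.Generator(np.random.PCG64(seed))
    events = list(truth.exon_baseline)
    sev = np.array([truth.severity[s] for s in truth.samples])
    base = np.array([truth.exon_baseline[e] for e in events])
    d = np.array([truth.exon_direction[e] for e in events])
    a = np.array([truth.exon_amplitude[e] for e in events])
    mu = np.clip(base[:, None] + (d * a)[:, None] * sev[None, :], 0.01, 0.99)
    values = rng.beta(mu * kappa, (1 - mu) * kappa)
    index = [event_prefix + e for e in events]
    return PsiMatrix(pd.DataFrame(values, index=index, columns=truth.samples),
                     dict(truth.groups))
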
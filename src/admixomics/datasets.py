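"""Synthetic cohort generators for the ancestry-stratified profiling pipeline.

No patient-level data from the motivating cohort is publicly available, so
every downstream stage is exercised on synthetic data whose statistical
structure matches the study design:

* a reference panel of ancestry-informative markers (AIMs) with
  population-specific alternate-allele frequencies drawn from the
  Balding-Nichols model around an ancestral frequency, one differentiation
  parameter ``F_k`` per population;
* genotype dosages drawn binomially given per-sample admixture proportions,
  the exact generative counterpart of the supervised admixture likelihood;
* clinical records (stage, subtype, grade, age) drawn from the published
  cohort composition of 623 African-ancestry (AA) and 2810
  European-ancestry (EA) breast-cancer patients;
* per-gene pathogenic-alteration carrier indicators drawn Bernoulli with
  group- and subtype-specific prevalences matching the published oncoplot
  frequencies (e.g. PIK3CA in HR+/HER2-: 34% AA vs 42% EA);
* negative-binomial RNA-seq counts with a two-level assay batch effect and
  a planted ancestry effect in a configurable fraction of genes, returned
  together with the true-effect registry so recovery can be scored.

All generators are pure functions of their inputs and a seed: repeated
calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "DEFAULT_CLINICAL_PROBS",
    "DEFAULT_PREVALENCES",
    "POPULATIONS",
    "make_reference_panel",
    "make_genotypes",
    "make_clinical",
    "make_mutations",
    "make_counts",
    "make_gene_sets",
]

#: Continental reference populations, fixed order (1000 Genomes super-populations).
POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

SUBTYPES = ("HRpos_HER2neg", "TNBC", "Other")
STAGES = ("0", "I", "II", "III", "IV")
GRADES = ("low", "high", "unknown")

# Cohort composition: counts out of 623 AA and 2810 EA patients.
_T1 = {
    "AA": {
        "n": 623,
        "stage": {"0": 0, "I": 11, "II": 48, "III": 45, "IV": 519},
        "subtype": {"HRpos_HER2neg": 221, "TNBC": 143, "Other": 259},
        "grade": {"low": 163, "high": 354, "unknown": 106},
        "age_mean": 54.01,
        "age_sd": 12.59,
    },
    "EA": {
        "n": 2810,
        "stage": {"0": 1, "I": 92, "II": 152, "III": 193, "IV": 2372},
        "subtype": {"HRpos_HER2neg": 1281, "TNBC": 400, "Other": 1129},
        "grade": {"low": 980, "high": 1198, "unknown": 632},
        "age_mean": 55.90,
        "age_sd": 13.37,
    },
}

#: Default per-group categorical probabilities for stage/subtype/grade and
#: normal age parameters, derived from the published cohort counts.
DEFAULT_CLINICAL_PROBS = {
    g: {
        "stage": {k: v / _T1[g]["n"] for k, v in _T1[g]["stage"].items()},
        "subtype": {k: v / _T1[g]["n"] for k, v in _T1[g]["subtype"].items()},
        "grade": {k: v / _T1[g]["n"] for k, v in _T1[g]["grade"].items()},
        "age_mean": _T1[g]["age_mean"],
        "age_sd": _T1[g]["age_sd"],
    }
    for g in ("AA", "EA")
}

# Carrier prevalences by (group, subtype); subtype-specific values from the
# published oncoplots, with the whole-cohort frequency standing in for the
# "Other" subtype where no stratified figure was printed.
_PREV_ROWS = [
    # gene, AA HR+, EA HR+, AA TNBC, EA TNBC, AA Other, EA Other
    ("TP53", 0.40, 0.37, 0.90, 0.88, 0.59, 0.49),
    ("PIK3CA", 0.34, 0.42, 0.16, 0.20, 0.28, 0.37),
    ("KMT2C", 0.24, 0.15, 0.23, 0.12, 0.20, 0.14),
    ("GATA3", 0.22, 0.14, 0.02, 0.02, 0.12, 0.10),
    ("PTEN", 0.06, 0.12, 0.12, 0.12, 0.09, 0.11),
    ("FGFR1", 0.18, 0.12, 0.08, 0.08, 0.12, 0.10),
    ("BRCA1", 0.03, 0.03, 0.08, 0.12, 0.05, 0.05),
    ("BRCA2", 0.07, 0.04, 0.05, 0.06, 0.05, 0.05),
    ("APOB", 0.06, 0.06, 0.13, 0.08, 0.07, 0.07),
    ("ESR1", 0.10, 0.12, 0.01, 0.01, 0.08, 0.09),
]

#: Default prevalence table: ``{gene: {(group, subtype): probability}}``.
DEFAULT_PREVALENCES = {
    gene: {
        ("AA", "HRpos_HER2neg"): a_hr,
        ("EA", "HRpos_HER2neg"): e_hr,
        ("AA", "TNBC"): a_tn,
        ("EA", "TNBC"): e_tn,
        ("AA", "Other"): a_ot,
        ("EA", "Other"): e_ot,
    }
    for gene, a_hr, e_hr, a_tn, e_tn, a_ot, e_ot in _PREV_ROWS
}


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: a 654-marker AIM panel over
    K=5 continental populations at moderate differentiation (F=0.15, a
    typical continental FST), the published clinical composition, the
    published oncoplot prevalences, and RNA-seq counts with a mild assay
    batch effect and a 5% fraction of genes carrying a |log2FC| = 2
    ancestry effect.

    Parameters
    ----------
    seed : master seed; identical configs with identical seeds produce
        bit-identical cohorts.
    n_AA, n_EA : patients per ancestry group.
    M : number of AIMs; K : number of reference populations.
    F : per-population Balding-Nichols differentiation, each in (0, 1).
    clinical_probs : per-group categorical probabilities (see
        :data:`DEFAULT_CLINICAL_PROBS`).
    prevalences : per-gene, per-(group, subtype) carrier probabilities.
    G : number of expression genes.
    de_fraction : fraction of genes with a planted ancestry effect.
    effect_size : |log2 fold-change| of planted effects (sign randomised).
    batch_effect_sd : SD of the per-gene log2 shift between assay versions.
    dispersion_meanlog, dispersion_sdlog : lognormal parameters of the
        per-gene NB dispersion phi (variance = mu + phi * mu^2).
    libsize_range : uniform bounds on per-sample library size.
    """

    seed: int = 0
    n_AA: int = 200
    n_EA: int = 200
    M: int = 654
    K: int = 5
    F: tuple = (0.15, 0.15, 0.15, 0.15, 0.15)
    clinical_probs: dict = field(default_factory=lambda: DEFAULT_CLINICAL_PROBS)
    prevalences: dict = field(default_factory=lambda: DEFAULT_PREVALENCES)
    G: int = 2000
    de_fraction: float = 0.05
    effect_size: float = 2.0
    batch_effect_sd: float = 0.25
    dispersion_meanlog: float = float(np.log(0.1))
    dispersion_sdlog: float = 0.5
    libsize_range: tuple = (5e6, 2e7)

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (self.K,):
            raise ValueError(f"F must have length K={self.K}")
        if not np.all(np.isfinite(F)) or np.any(F <= 0) or np.any(F >= 1):
            raise ValueError("all F_k must be finite and strictly in (0, 1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.M < 1 or self.K < 1 or self.G < 10:
            raise ValueError("require M >= 1, K >= 1, G >= 10")
        if self.n_AA <= 0 or self.n_EA <= 0:
            raise ValueError("group sizes must be positive")
        lo, hi = self.libsize_range
        if not (0 < lo < hi):
            raise ValueError("libsize_range must satisfy 0 < lo < hi")
        for g, probs in self.clinical_probs.items():
            for var in ("stage", "subtype", "grade"):
                vec = np.array(list(probs[var].values()), dtype=float)
                if np.any(vec < 0) or np.any(vec > 1):
                    raise ValueError(f"{g}/{var} probabilities outside [0, 1]")
                if abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{g}/{var} probabilities must sum to 1")
        for gene, table in self.prevalences.items():
            for key, pr in table.items():
                if not 0.0 <= pr <= 1.0:
                    raise ValueError(f"prevalence for {gene}/{key} outside [0, 1]")


_FREQ_CLAMP = 1e-6


def make_reference_panel(M: int, K: int = 5, F=(0.15,) * 5, seed: int = 0) -> pd.DataFrame:
    """Simulate an AIM reference panel under the Balding-Nichols model.

    Each marker has an ancestral alternate-allele frequency
    ``f ~ Uniform(0.05, 0.95)``; population k's frequency is drawn
    ``Beta(f (1-F_k)/F_k, (1-f)(1-F_k)/F_k)`` so that ``E[f_k] = f`` and
    ``Var[f_k] = F_k f (1-f)`` — F_k plays the role of FST against the
    ancestral population. Frequencies are clamped to
    ``[1e-6, 1 - 1e-6]`` to keep the genotype log-likelihood finite.

    Returns a DataFrame with columns ``chrom, pos, ref, alt`` followed by
    one frequency column per population (``f_AFR`` ... for K=5, else
    ``f_POP1`` ...).
    """
    if M < 1 or K < 1:
        raise ValueError("require M >= 1 and K >= 1")
    F = np.asarray(F, dtype=float)
    if F.shape != (K,):
        raise ValueError(f"F must have length K={K}")
    if not np.all(np.isfinite(F)) or np.any(F <= 0) or np.any(F >= 1):
        raise ValueError("all F_k must be finite and strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=M)
    freqs = np.empty((M, K))
    for k in range(K):
        ratio = (1.0 - F[k]) / F[k]
        freqs[:, k] = rng.beta(anc * ratio, (1.0 - anc) * ratio)
    freqs = np.clip(freqs, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=M)
    alt_idx = (ref_idx + rng.integers(1, 4, size=M)) % 4
    chrom = (np.arange(M) % 22 + 1).astype(str)
    pos = 1 + np.arange(M) * 1000 + rng.integers(0, 1000, size=M)

    names = POPULATIONS if K == 5 else tuple(f"POP{k + 1}" for k in range(K))
    panel = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx]})
    for k, name in enumerate(names):
        panel[f"f_{name}"] = freqs[:, k]
    return panel


def panel_frequencies(panel: pd.DataFrame) -> np.ndarray:
    """Extract the M x K frequency matrix from a panel DataFrame."""
    cols = [c for c in panel.columns if c.startswith("f_")]
    if not cols:
        raise ValueError("panel has no frequency columns (f_*)")
    return panel[cols].to_numpy(dtype=float)


def make_genotypes(panel: pd.DataFrame, q_matrix, seed: int = 0) -> pd.DataFrame:
    """Draw alt-allele dosages ``g ~ Binomial(2, sum_k q_k f_km)``.

    ``q_matrix`` is samples x K; every row must lie on the simplex (sum to
    1 within 1e-6, non-negative).
    """
    freqs = panel_frequencies(panel)
    q = np.asarray(q_matrix, dtype=float)
    if q.ndim != 2 or q.shape[1] != freqs.shape[1]:
        raise ValueError("q_matrix must be samples x K matching the panel")
    if np.any(q < 0) or np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each q row must be a probability vector summing to 1")
    rng = np.random.default_rng(seed)
    p = q @ freqs.T  # samples x markers
    dosages = rng.binomial(2, p)
    index = [f"S{i:04d}" for i in range(q.shape[0])]
    cols = [f"m{j:04d}" for j in range(freqs.shape[0])]
    return pd.DataFrame(dosages, index=index, columns=cols)


def _draw_categorical(rng, levels, probs, size):
    p = np.array([probs[lv] for lv in levels], dtype=float)
    return rng.choice(len(levels), size=size, p=p / p.sum())


def make_clinical(
    n_AA: int, n_EA: int, probs: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw per-patient clinical records for the two ancestry groups.

    Stage, subtype and grade are independent categorical draws with the
    per-group probabilities in ``probs`` (default: the published cohort
    composition); age is normal with the per-group mean/SD, truncated at 18.
    """
    if n_AA <= 0 or n_EA <= 0:
        raise ValueError("group sizes must be positive")
    if probs is None:
        probs = DEFAULT_CLINICAL_PROBS
    rng = np.random.default_rng(seed)
    frames = []
    for group, n in (("AA", n_AA), ("EA", n_EA)):
        gp = probs[group]
        stage = _draw_categorical(rng, STAGES, gp["stage"], n)
        subtype = _draw_categorical(rng, SUBTYPES, gp["subtype"], n)
        grade = _draw_categorical(rng, GRADES, gp["grade"], n)
        age = np.maximum(18.0, rng.normal(gp["age_mean"], gp["age_sd"], size=n))
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{group}{i:05d}" for i in range(n)],
                    "age": np.round(age, 2),
                    "stage": np.array(STAGES)[stage],
                    "subtype": np.array(SUBTYPES)[subtype],
                    "grade": np.array(GRADES)[grade],
                    "group": group,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_mutations(
    clinical: pd.DataFrame, prevalences: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw the patients x genes boolean pathogenic-carrier matrix.

    Each entry is Bernoulli with probability ``prevalences[gene][(group,
    subtype)]``; genes with no entry for a patient's (group, subtype) key
    default to never-mutated. Unknown group or subtype values in the
    clinical table raise.
    """
    if prevalences is None:
        prevalences = DEFAULT_PREVALENCES
    bad_group = set(clinical["group"]) - {"AA", "EA"}
    bad_sub = set(clinical["subtype"]) - set(SUBTYPES)
    if bad_group or bad_sub:
        raise ValueError(f"unknown group/subtype keys: {bad_group | bad_sub}")
    rng = np.random.default_rng(seed)
    genes = list(prevalences)
    n = len(clinical)
    out = np.zeros((n, len(genes)), dtype=bool)
    keys = list(zip(clinical["group"], clinical["subtype"]))
    for j, gene in enumerate(genes):
        table = prevalences[gene]
        p = np.array([table.get(key, 0.0) for key in keys])
        out[:, j] = rng.random(n) < p
    return pd.DataFrame(out, index=clinical["patient_id"].to_numpy(), columns=genes)


def make_counts(clinical: pd.DataFrame, cfg: SimConfig):
    """Simulate the genes x samples RNA-seq count matrix with batch effects.

    Model, per gene g and sample j::

        log2 mu_gj = baseline_g + b_g * [batch_j = v2]
                     + beta_g * [group_j = AA] + log2(libsize_j / 1e6)
        count_gj ~ NegativeBinomial(mean = 2**log2 mu_gj, dispersion phi_g)

    with variance ``mu + phi mu^2``, ``phi_g`` lognormal, batch v1/v2
    assigned Bernoulli(0.5) per sample (the study reported a near-50/50
    assay split in both groups), and ``beta_g = +/- effect_size`` for a
    ``de_fraction`` subset of genes (zero otherwise).

    Returns
    -------
    counts : DataFrame, genes x samples (integer).
    samples : DataFrame with ``sample, group, batch, libsize``.
    truth : DataFrame with ``gene, beta`` — the planted-effect registry.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.libsize_range
    if not (0 < lo < hi):
        raise ValueError("degenerate libsize_range")
    G = cfg.G
    ids = clinical["patient_id"].to_numpy()
    group_aa = (clinical["group"] == "AA").to_numpy()
    n = len(ids)

    batch = np.where(rng.random(n) < 0.5, "v1", "v2")
    libsize = rng.uniform(lo, hi, size=n)

    baseline = rng.uniform(1.0, 9.0, size=G)  # log2 CPM scale
    b = rng.normal(0.0, cfg.batch_effect_sd, size=G) if cfg.batch_effect_sd > 0 else np.zeros(G)
    beta = np.zeros(G)
    n_de = int(round(cfg.de_fraction * G))
    if n_de:
        de_idx = rng.choice(G, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        beta[de_idx] = signs * cfg.effect_size
    phi = rng.lognormal(cfg.dispersion_meanlog, cfg.dispersion_sdlog, size=G)

    log2mu = (
        baseline[:, None]
        + b[:, None] * (batch == "v2")[None, :]
        + beta[:, None] * group_aa[None, :]
        + np.log2(libsize / 1e6)[None, :]
    )
    mu = np.exp2(log2mu)
    r = 1.0 / phi[:, None]  # NB size parameter
    counts = rng.negative_binomial(r, r / (r + mu))

    genes = [f"G{g:05d}" for g in range(G)]
    counts_df = pd.DataFrame(counts, index=genes, columns=ids)
    samples = pd.DataFrame(
        {"sample": ids, "group": clinical["group"].to_numpy(), "batch": batch, "libsize": libsize}
    )
    truth = pd.DataFrame({"gene": genes, "beta": beta})
    return counts_df, samples, truth


def make_gene_sets(
    genes,
    n_hallmark: int = 50,
    n_oncogenic: int = 189,
    size_range: tuple = (25, 200),
    seed: int = 0,
) -> dict:
    """Generate a synthetic gene-set collection over a gene universe.

    Emulates the composition of the hallmark (50 sets) plus oncogenic
    signature (189 sets) collections used for single-sample enrichment:
    239 sets of uniformly drawn sizes, sampled without replacement from the
    supplied universe. Membership is random — the sets carry no biology,
    only the combinatorial structure needed to test scoring and
    family-size bookkeeping.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(genes) - 1)  # a set must never cover the whole universe
    if lo > hi:
        raise ValueError("size_range incompatible with gene universe")
    sets = {}
    for i in range(n_hallmark):
        size = int(rng.integers(lo, hi + 1))
        sets[f"HALLMARK_SYNTH_{i:03d}"] = list(rng.choice(genes, size=size, replace=False))
    for i in range(n_oncogenic):
        size = int(rng.integers(lo, hi + 1))
        sets[f"ONCOSIG_SYNTH_{i:03d}"] = list(rng.choice(genes, size=size, replace=False))
    return sets
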
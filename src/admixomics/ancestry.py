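"""Supervised genetic-ancestry inference from ancestry-informative markers.

Given a panel of AIMs with known alternate-allele frequencies ``f_km`` in
K reference populations (here the five 1000 Genomes continental groups:
Africa, Americas, East Asia, Europe, South Asia) and a sample's alt-allele
dosages ``g_m`` in {0, 1, 2}, the per-sample admixture proportion vector
``q`` on the K-simplex maximises the binomial genotype log-likelihood

    l(q) = sum_m [ g_m ln a_m + (2 - g_m) ln(1 - a_m) ],
    a_m  = sum_k q_k f_km.

This is the supervised (fixed-frequency) admixture problem; l is concave
in q, so the EM fixed-point iteration

    q_k <- (1 / 2M') sum_m [ g_m q_k f_km / a_m
                             + (2 - g_m) q_k (1 - f_km) / (1 - a_m) ]

from the uniform start converges to the global maximiser without restarts
(M' = markers with a non-missing dosage; missing markers are dropped, not
imputed). Samples are then assigned to the African-ancestry (AA) or
European-ancestry (EA) analysis group by strict thresholds on q, or
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import panel_frequencies

__all__ = [
    "AncestryThresholds",
    "load_aim_panel",
    "SupervisedAdmixture",
    "estimate_admixture",
    "classify_ancestry",
    "concordance",
]

_CLAMP = 1e-6


@dataclass(frozen=True)
class AncestryThresholds:
    """Admixture-proportion thresholds for AA/EA group assignment.

    AA requires African > ``afr_min``, Americas < ``amr_max`` and
    African + European > ``afr_plus_eur_min``; EA requires European >
    ``eur_min`` and Americas < ``amr_max``. All inequalities are strict,
    so boundary values are excluded.
    """

    afr_min: float = 0.20
    amr_max: float = 0.10
    afr_plus_eur_min: float = 0.70
    eur_min: float = 0.80

    def __post_init__(self):
        for v in (self.afr_min, self.amr_max, self.afr_plus_eur_min, self.eur_min):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie strictly in (0, 1)")


def load_aim_panel(path) -> pd.DataFrame:
    """Load and validate a tab-separated AIM panel.

    Expected columns: ``chrom, pos, ref, alt`` (1-based VCF-style
    coordinates) plus one ``f_<POP>`` alternate-allele frequency column
    per reference population. Frequencies outside [0, 1] and duplicate
    markers raise a parse error naming the offending line; valid
    frequencies are clamped to ``[1e-6, 1 - 1e-6]`` so the genotype
    log-likelihood stays finite at fixed alleles.
    """
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required column(s): {missing}")
    fcols = [c for c in panel.columns if c.startswith("f_")]
    if not fcols:
        raise ValueError("panel has no frequency columns (expected f_<POP>)")

    key = panel[required].astype(str).agg(":".join, axis=1)
    dup = key.duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"duplicate marker {key[dup].iloc[0]!r} at line {line}")

    freqs = panel[fcols].to_numpy(dtype=float)
    bad = ~np.isfinite(freqs) | (freqs < 0.0) | (freqs > 1.0)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"allele frequency outside [0, 1] at line {row + 2} (marker {key.iloc[row]!r})"
        )
    panel = panel.copy()
    panel[fcols] = np.clip(freqs, _CLAMP, 1.0 - _CLAMP)
    return panel


class SupervisedAdmixture:
    """Supervised admixture-proportion estimator (scikit-learn style).

    Parameters
    ----------
    panel : DataFrame
        AIM panel with ``f_<POP>`` frequency columns (see
        :func:`load_aim_panel`); frequencies are held fixed.
    tol : float
        EM stops when the log-likelihood improvement drops below ``tol``.
        The criterion is on the objective, not on q.
    max_iter : int
        Iteration cap per sample.

    Attributes (after :meth:`fit`)
    ------------------------------
    proportions_ : ndarray (n_samples, K) — admixture vectors on the simplex.
    loglik_ : ndarray (n_samples,) — final log-likelihood per sample.
    n_iter_ : ndarray (n_samples,) — EM iterations used.
    converged_ : ndarray (n_samples,) bool.
    n_markers_used_ : ndarray (n_samples,) — non-missing markers per sample.
    populations_ : tuple of population names, panel column order.
    """

    def __init__(self, panel: pd.DataFrame, tol: float = 1e-8, max_iter: int = 1000):
        self.panel = panel
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"panel": self.panel, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("panel", "tol", "max_iter"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validate(self, X):
        F = np.clip(panel_frequencies(self.panel), _CLAMP, 1.0 - _CLAMP)
        if isinstance(X, pd.DataFrame):
            G = X.to_numpy(dtype=float)
        else:
            G = np.asarray(X, dtype=float)
        if G.ndim != 2:
            raise ValueError("genotype matrix must be 2-d (samples x markers)")
        if G.shape[1] != F.shape[0]:
            raise ValueError(
                f"genotypes have {G.shape[1]} markers but the panel has {F.shape[0]}"
            )
        obs = ~np.isnan(G)
        vals = G[obs]
        if vals.size and (np.any(~np.isin(vals, (0.0, 1.0, 2.0)))):
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        return G, F, obs

    def fit(self, X, y=None):
        """Run the EM to convergence for every sample in X.

        X is samples x markers with dosages in {0, 1, 2}; missing dosages
        are NaN and are dropped per sample. A sample with no observed
        marker cannot be estimated: its row is NaN, flagged unconverged,
        and a warning is raised while the remaining samples proceed.
        """
        G, F, obs = self._validate(X)
        n, M = G.shape
        K = F.shape[1]
        Mprime = obs.sum(axis=1)
        all_missing = Mprime == 0
        if all_missing.any():
            warnings.warn(
                f"{int(all_missing.sum())} sample(s) have no observed markers; "
                "their estimates are NaN"
            )

        Gz = np.where(obs, G, 0.0)  # masked dosage / complement
        Cz = np.where(obs, 2.0 - G, 0.0)

        q = np.full((n, K), 1.0 / K)
        loglik = np.full(n, -np.inf)
        n_iter = np.zeros(n, dtype=int)
        converged = np.zeros(n, dtype=bool)
        active = ~all_missing

        def _loglik(qm, rows):
            a = qm[rows] @ F.T
            return (Gz[rows] * np.log(a) + Cz[rows] * np.log1p(-a)).sum(axis=1)

        loglik[active] = _loglik(q, active)
        for it in range(1, self.max_iter + 1):
            rows = np.flatnonzero(active)
            if rows.size == 0:
                break
            a = q[rows] @ F.T  # (r, M)
            A = Gz[rows] / a
            B = Cz[rows] / (1.0 - a)
            T = q[rows] * (A @ F + B @ (1.0 - F))
            q_new = T / (2.0 * Mprime[rows, None])
            # guard drift off the simplex from floating-point accumulation
            q_new /= q_new.sum(axis=1, keepdims=True)
            ll_new = (Gz[rows] * np.log(q_new @ F.T) + Cz[rows] * np.log1p(-(q_new @ F.T))).sum(
                axis=1
            )
            delta = ll_new - loglik[rows]
            q[rows] = q_new
            loglik[rows] = ll_new
            n_iter[rows] = it
            done = delta < self.tol
            converged[rows[done]] = True
            active[rows[done]] = False

        q[all_missing] = np.nan
        loglik[all_missing] = np.nan

        self.proportions_ = q
        self.loglik_ = loglik
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_markers_used_ = Mprime
        fcols = [c for c in self.panel.columns if c.startswith("f_")]
        self.populations_ = tuple(c[2:] for c in fcols)
        return self

    def transform(self, X=None):
        """Return the fitted proportions as a DataFrame (populations as columns)."""
        if not hasattr(self, "proportions_"):
            raise AttributeError("SupervisedAdmixture is not fitted yet; call fit first")
        idx = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(self.proportions_, columns=list(self.populations_), index=idx)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def estimate_admixture(
    genotypes, panel: pd.DataFrame, tol: float = 1e-8, max_iter: int = 1000
) -> pd.DataFrame:
    """Per-sample admixture estimates as a tidy DataFrame.

    Thin wrapper over :class:`SupervisedAdmixture`; returns one row per
    sample with the q components (named by population), ``loglik``,
    ``n_iter``, ``converged`` and ``n_markers_used``.
    """
    est = SupervisedAdmixture(panel, tol=tol, max_iter=max_iter).fit(genotypes)
    out = est.transform(genotypes if isinstance(genotypes, pd.DataFrame) else None)
    out["loglik"] = est.loglik_
    out["n_iter"] = est.n_iter_
    out["converged"] = est.converged_
    out["n_markers_used"] = est.n_markers_used_
    return out


def classify_ancestry(q, thresholds: AncestryThresholds | None = None) -> str:
    """Assign an admixture vector to {"AA", "EA", "EXCLUDED"}.

    ``q`` must expose named components AFR, AMR, EAS, EUR, SAS (mapping or
    pandas Series). AA: African > 20%, Americas < 10%, African + European
    > 70%. EA: European > 80%, Americas < 10%. All strict; anything else —
    including exact boundary values — is EXCLUDED. The two rules are
    mutually exclusive (African > 20% forces European < 80%).
    """
    thr = thresholds or AncestryThresholds()
    try:
        afr, amr, eur = float(q["AFR"]), float(q["AMR"]), float(q["EUR"])
    except (KeyError, IndexError, TypeError) as exc:
        raise ValueError("q must have named components AFR, AMR, EAS, EUR, SAS") from exc
    if not np.isfinite([afr, amr, eur]).all():
        raise ValueError("q contains non-finite components")
    if afr > thr.afr_min and amr < thr.amr_max and (afr + eur) > thr.afr_plus_eur_min:
        return "AA"
    if eur > thr.eur_min and amr < thr.amr_max:
        return "EA"
    return "EXCLUDED"


def concordance(est_a: pd.DataFrame, est_b: pd.DataFrame, populations=None) -> pd.DataFrame:
    """Per-population Pearson correlation of admixture estimates.

    Used to compare estimates from two specimens of the same patients
    (e.g. tumour vs matched normal). A population whose proportion is
    constant in either set has an undefined correlation: it is reported
    as NaN with ``defined=False``, never as 1.
    """
    pops = list(populations) if populations is not None else [
        c for c in est_a.columns if c in est_b.columns and c.isupper()
    ]
    if not pops:
        raise ValueError("no shared population columns between the two estimates")
    if len(est_a) != len(est_b):
        raise ValueError("estimate sets must cover the same samples")
    if len(est_a) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rows = []
    for p in pops:
        x = est_a[p].to_numpy(dtype=float)
        y = est_b[p].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append({"population": p, "r": np.nan, "defined": False})
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"population": p, "r": r, "defined": True})
    return pd.DataFrame(rows).set_index("population")
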
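"""Single-sample gene-set enrichment (ssGSEA) and group comparison.

ssGSEA scores each (sample, gene set) pair by how coordinately the set's
genes sit at the top or bottom of that sample's expression ranking. Per
sample, genes are ranked by expression (average ranks for ties) and walked
in descending order; the score is the sum over positions of the gap
between the weighted in-set ECDF (rank values raised to ``alpha``) and the
unweighted out-of-set ECDF:

    ES(S, j) = sum_i [ P_in^w(i) - P_out(i) ],
    P_in^w(i) = sum_{g in S, pos(g) <= i} r_g^alpha / sum_{g in S} r_g^alpha,
    P_out(i)  = #{g not in S, pos(g) <= i} / (N - |S|).

Because only within-sample ranks enter, scores are invariant to any
strictly increasing transform of a sample's expression values. With
``normalize=True`` the whole score matrix is divided by its (max - min),
a single global scalar that preserves ordering.

Scores are compared between ancestry groups per set with the moderated t
from :mod:`admixomics.demeta` under a Bonferroni cutoff
``alpha_family / n_sets`` (0.01 / 239 sets = 4.18e-05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .demeta import ModeratedTTest

__all__ = ["GeneSetCollection", "read_gmt", "SSGSEA", "ssgsea_scores", "compare_enrichment"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus a collection label (hallmark | oncogenic | custom)."""

    sets: dict
    label: str = "custom"

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, label: str = "custom") -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Duplicate genes within a set are deduplicated (first occurrence kept);
    a duplicate set name or a line with fewer than three fields raises a
    parse error with its line number.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return GeneSetCollection(sets=sets, label=label)


def write_gmt(collection, path) -> None:
    """Write a mapping of set name -> genes (or a GeneSetCollection) as GMT."""
    items = collection if isinstance(collection, dict) else collection.sets
    with open(path, "w") as fh:
        for name, genes in items.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


class SSGSEA:
    """ssGSEA score transformer (scikit-learn style).

    Parameters
    ----------
    gene_sets : GeneSetCollection or dict of name -> genes.
    alpha : rank-weight exponent (0.25 by default, the single-sample
        convention; ``alpha=0`` gives the unweighted Kolmogorov-Smirnov
        style running sum).
    normalize : divide the final score matrix by its global (max - min).

    ``fit`` intersects each set with the expression matrix's gene index
    (empty intersections dropped with a warning; a set covering every
    gene raises since the out-of-set ECDF is then undefined);
    ``transform`` returns the sets x samples score matrix.
    """

    def __init__(self, gene_sets, alpha: float = 0.25, normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def get_params(self, deep: bool = True) -> dict:
        return {"gene_sets": self.gene_sets, "alpha": self.alpha, "normalize": self.normalize}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("gene_sets", "alpha", "normalize"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _sets_dict(self) -> dict:
        return self.gene_sets.sets if isinstance(self.gene_sets, GeneSetCollection) else dict(self.gene_sets)

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise ValueError("expression matrix must be a DataFrame (genes x samples)")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 genes")
        genes = X.index
        pos = pd.Series(np.arange(len(genes)), index=genes)
        members = {}
        dropped = []
        for name, gl in self._sets_dict().items():
            idx = pos.reindex(pd.unique(pd.Index(gl))).dropna().to_numpy(dtype=int)
            if idx.size == 0:
                dropped.append(name)
                continue
            if idx.size == len(genes):
                raise ValueError(f"gene set {name!r} covers every gene; score undefined")
            members[name] = idx
        if dropped:
            warnings.warn(f"dropping {len(dropped)} set(s) with no genes in the matrix")
        if not members:
            raise ValueError("no gene set overlaps the expression matrix")
        self.members_ = members
        self.genes_ = genes
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "members_"):
            raise AttributeError("SSGSEA is not fitted yet; call fit first")
        if not X.index.equals(self.genes_):
            raise ValueError("gene index differs from the fitted matrix")
        E = X.to_numpy(dtype=float)
        N, n_samples = E.shape
        set_names = list(self.members_)
        n_sets = len(set_names)
        # boolean membership matrix in original gene order
        memb = np.zeros((n_sets, N), dtype=bool)
        for s, name in enumerate(set_names):
            memb[s, self.members_[name]] = True
        sizes = memb.sum(axis=1)

        scores = np.empty((n_sets, n_samples))
        for j in range(n_samples):
            ranks = sps.rankdata(E[:, j])  # average ranks, 1..N (ties averaged)
            order = np.argsort(-ranks, kind="stable")  # descending expression
            w = ranks[order] ** self.alpha
            B = memb[:, order]
            Win = np.where(B, w[None, :], 0.0)
            denom_in = Win.sum(axis=1, keepdims=True)
            P_in = np.cumsum(Win, axis=1) / denom_in
            P_out = np.cumsum(~B, axis=1) / (N - sizes)[:, None]
            scores[:, j] = (P_in - P_out).sum(axis=1)

        if self.normalize:
            span = scores.max() - scores.min()
            if span > 0:
                scores = scores / span
        return pd.DataFrame(scores, index=set_names, columns=X.columns)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def ssgsea_scores(expr: pd.DataFrame, gene_sets, alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """Sets x samples ssGSEA score matrix (wrapper over :class:`SSGSEA`)."""
    return SSGSEA(gene_sets, alpha=alpha, normalize=normalize).fit_transform(expr)


def compare_enrichment(
    scores: pd.DataFrame, groups, alpha_family: float = 0.01, reference: str = "EA"
) -> pd.DataFrame:
    """Compare per-set enrichment between ancestry groups.

    Moderated t across sets (variance moderation borrowed from the
    differential-expression machinery), reference group subtracted so a
    positive logFC means higher enrichment in AA. Significance uses the
    Bonferroni cutoff ``alpha_family / n_sets`` over the sets actually
    tested; the full table is returned regardless.
    """
    groups = np.asarray(groups)
    if len(set(groups)) < 2:
        raise ValueError("need two groups to compare enrichment")
    fit = ModeratedTTest(reference=reference).fit(scores, groups)
    n_sets = scores.shape[0]
    cutoff = alpha_family / n_sets
    out = pd.DataFrame(
        {
            "logFC": fit.logfc_,
            "t": fit.t_,
            "p": fit.p_,
            "significant": fit.p_ < cutoff,
        },
        index=scores.index,
    )
    out.attrs["cutoff"] = cutoff
    out.attrs["n_sets"] = n_sets
    out.attrs["alpha_family"] = alpha_family
    return out
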
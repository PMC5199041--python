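"""Core-vs-mobile classification and population statistics.

Horizontally transferred loci in *Bacillus* sit in AT-rich islands, so a
cassette whose gene GC is significantly below its strain's gene-GC
distribution is called *mobile* (one-sided z-test, default alpha 0.05;
cluster-level labels by majority vote of member cassettes). Independent of
GC, mobile clusters show up at low within-species frequencies in the
presence/absence association matrix, and cluster discovery as a function of
sampled strains (the rarefaction curve) keeps climbing when diversity is
unsaturated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ConfigError, InputError, UndefinedScoreError, substream
from .sequences import gc_fraction  # re-exported: GC analyses live together here

__all__ = [
    "gc_fraction", "GCProfile", "MobilityCall", "mobility_call",
    "strain_gene_gc", "neighborhood_gc", "neighborhood_gc_regression",
    "build_association_matrix", "duplicate_cluster_cases",
    "per_species_frequency", "RarefactionCurve", "rarefaction_curve",
    "cluster_mobility_labels",
]


@dataclass
class GCProfile:
    gene_gc: float
    strain_mean: float
    strain_sd: float
    neighborhood_gc: float | None = None


@dataclass
class MobilityCall:
    label: str                     # "core" | "mobile"
    p_value: float                 # NaN when the strain distribution is degenerate
    z_score: float


def strain_gene_gc(gene_gcs) -> tuple[float, float]:
    """Mean and sd of a strain's gene-GC distribution (>= 20 genes)."""
    arr = np.asarray(list(gene_gcs), float)
    if arr.size < 20:
        raise InputError("need >= 20 genes to characterize the strain GC distribution")
    return float(arr.mean()), float(arr.std(ddof=1))


def mobility_call(gene_gc: float, strain_mean: float, strain_sd: float,
                  alpha: float = 0.05) -> MobilityCall:
    """One-sided z-test of a gene's GC below the strain mean.

    Degenerate distributions (sd = 0) are labeled by strict inequality with
    an undefined (NaN) p-value.
    """
    if strain_sd == 0:
        label = "mobile" if gene_gc < strain_mean else "core"
        return MobilityCall(label, float("nan"),
                            -np.inf if gene_gc < strain_mean else 0.0)
    z = (gene_gc - strain_mean) / strain_sd
    p = float(stats.norm.cdf(z))
    return MobilityCall("mobile" if p < alpha else "core", p, float(z))


def cluster_mobility_labels(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster core/mobile labels by majority vote of member cassettes.

    ``table`` needs columns: cluster, gene_gc, strain_mean, strain_sd.
    Returns one row per cluster with the vote fraction and the mean z-score.
    """
    rows = []
    for cluster, grp in table.groupby("cluster"):
        calls = [mobility_call(r.gene_gc, r.strain_mean, r.strain_sd, alpha)
                 for r in grp.itertuples()]
        mobile_frac = np.mean([c.label == "mobile" for c in calls])
        rows.append({
            "cluster": cluster,
            "label": "mobile" if mobile_frac > 0.5 else "core",
            "mobile_vote": float(mobile_frac),
            "mean_z": float(np.mean([c.z_score for c in calls])),
            "n_members": len(calls),
        })
    return pd.DataFrame(rows).set_index("cluster")


def neighborhood_gc(contig: str, gene_start: int, strand: int,
                    window: tuple[int, int] = (-1000, -300)) -> float | None:
    """GC of the upstream neighborhood window (default 1 kb to 300 bp
    upstream of the gene start, in gene orientation)."""
    if strand == 1:
        lo, hi = gene_start + window[0], gene_start + window[1]
    else:
        lo, hi = gene_start - window[1], gene_start - window[0]
    lo, hi = max(0, lo), min(len(contig), hi)
    if hi - lo < 50:
        return None
    return gc_fraction(contig[lo:hi])


def neighborhood_gc_regression(pairs) -> tuple[float, float]:
    """Least-squares slope through the origin of gene GC on neighborhood GC,
    with the uncentered R-squared of that fit (1 - SS_res / sum y^2),
    clamped at 0."""
    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InputError("need >= 3 (gene GC, neighborhood GC) pairs")
    y, x = arr[:, 0], arr[:, 1]
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise UndefinedScoreError("all-zero predictor")
    slope = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, max(0.0, r2)


# ---------------------------------------------------------------------------
# association matrix and frequency statistics


def build_association_matrix(cassette_table: pd.DataFrame,
                             strains: list[str] | None = None,
                             ) -> pd.DataFrame:
    """Binary strains x clusters presence matrix (entry 1 iff >= 1 member)."""
    if len(cassette_table) == 0:
        idx = pd.Index(strains or [], name="strain")
        return pd.DataFrame(index=idx)
    if {"strain", "cluster"} - set(cassette_table.columns):
        raise InputError("cassette table needs 'strain' and 'cluster' columns")
    m = (pd.crosstab(cassette_table["strain"], cassette_table["cluster"]) > 0).astype(int)
    if strains is not None:
        m = m.reindex(index=strains, fill_value=0)
    m.index.name = "strain"
    return m


def duplicate_cluster_cases(cassette_table: pd.DataFrame,
                            ) -> tuple[int, int, pd.DataFrame]:
    """(strain, cluster) pairs carrying >= 2 cassettes of one cluster.

    Returns (non-orphan case count, orphan case count, case table); orphan
    duplicates — same-cluster receptors without propeptides — are counted
    separately.
    """
    if len(cassette_table) == 0:
        return 0, 0, pd.DataFrame(columns=["strain", "cluster", "n", "orphan"])
    counts = (cassette_table.groupby(["strain", "cluster"])
              .agg(n=("cluster", "size"), orphan=("orphan", "all"))
              .reset_index())
    cases = counts[counts["n"] >= 2].reset_index(drop=True)
    n_orphan = int(cases["orphan"].sum())
    return len(cases) - n_orphan, n_orphan, cases


def per_species_frequency(matrix: pd.DataFrame,
                          species: pd.Series) -> pd.DataFrame:
    """Within-species presence frequency per cluster, plus the cross-species
    mean over species where the cluster occurs at all."""
    if not matrix.index.equals(species.index):
        species = species.reindex(matrix.index)
    if species.isna().any():
        raise InputError("species label missing for some strains")
    freq = matrix.groupby(species.values).mean()
    freq.index.name = "species"
    occupied = freq.where(freq > 0)
    out = freq.T
    out["mean_frequency"] = occupied.mean(axis=0, skipna=True).fillna(0.0)
    out.index.name = "cluster"
    return out


# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefactionCurve:
    sizes: np.ndarray
    mean_clusters: np.ndarray
    n_resamples: int
    seed: int
    tail_slope: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group_size": self.sizes,
                             "mean_clusters": self.mean_clusters})


def rarefaction_curve(matrix: pd.DataFrame, n_resamples: int = 500,
                      tail_window: int = 20, seed: int = 0) -> RarefactionCurve:
    """Cluster accumulation curve over random strain orderings.

    For each group size k, the value is the mean number of distinct clusters
    among the first k strains of ``n_resamples`` random permutations; nested
    prefixes make the curve monotone by construction and its endpoint equal
    to the total number of observed clusters. The tail slope is the
    least-squares slope over the last ``tail_window`` group sizes.
    """
    n = matrix.shape[0]
    if n < 2:
        raise InputError("need at least two strains")
    if tail_window >= n:
        raise InputError("tail_window must be smaller than the number of strains")
    if n_resamples < 1:
        raise ConfigError("n_resamples must be positive")
    rng = substream(seed, "rarefaction")
    pres = matrix.to_numpy() > 0
    acc = np.zeros(n)
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        seen = np.zeros(pres.shape[1], bool)
        for k, row in enumerate(perm):
            seen |= pres[row]
            acc[k] += seen.sum()
    mean_clusters = acc / n_resamples
    sizes = np.arange(1, n + 1)
    tail = slice(n - tail_window, n)
    slope = float(np.polyfit(sizes[tail], mean_clusters[tail], 1)[0])
    return RarefactionCurve(sizes, mean_clusters, n_resamples, seed, slope)


def plot_rarefaction(curve: RarefactionCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.sizes, curve.mean_clusters, lw=2)
    ax.set_xlabel("number of strains sampled")
    ax.set_ylabel("distinct clusters discovered")
    ax.set_title(f"tail slope {curve.tail_slope:.2f} clusters/strain")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
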
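"""Variance-standardized genetic relationship matrix and PCA.

G_jk = (1/M) sum_i (g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i (1 - p_i)) over the
M polymorphic sites, with p_i the cohort alt-allele frequency; the diagonal
is approximately 1 + F. Principal components are the eigenvectors of G scaled
by the square root of their eigenvalues, and the explained fraction of
component k is lambda_k over the sum of positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeMatrix
from .variant_qc import alt_allele_frequencies


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PC1..PCk
    explained: np.ndarray  # fraction of total variance per component
    n_components: int

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "explained": [float(x) for x in self.explained],
        }


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """Variance-standardized relationship matrix over polymorphic sites.

    Missing dosages are mean-imputed per site (they contribute zero to the
    cross-product); monomorphic sites are skipped, their count stored on the
    result as ``grm.n_skipped_monomorphic``.
    """
    p = alt_allele_frequencies(gm.dosages)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    grm.n_skipped_monomorphic = int((~poly).sum())  # type: ignore[attr-defined]
    if poly.sum() < 2:
        raise ValueError("GRM needs at least 2 polymorphic sites")
    d = gm.dosages[:, poly].astype(float)
    p = p[poly]
    d[gm.dosages[:, poly] == MISSING] = np.nan
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.nan_to_num(z)
    m = z.shape[1]
    return (z @ z.T) / m


def pca(grm_matrix: np.ndarray, n_components: int = 10) -> PCAResult:
    """Eigendecomposition of a (symmetric) GRM.

    Scores are eigenvectors scaled by sqrt(eigenvalue); each eigenvector's
    sign is fixed so its largest-magnitude loading is positive.
    """
    G = np.asarray(grm_matrix, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    n_components = min(n_components, len(vals))
    pos_sum = vals[vals > 0].sum()
    explained = np.maximum(vals[:n_components], 0.0) / (
        pos_sum if pos_sum > 0 else 1.0
    )
    scores = np.empty((G.shape[0], n_components))
    for k in range(n_components):
        v = vecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        scores[:, k] = v * np.sqrt(max(vals[k], 0.0))
    frame = pd.DataFrame(
        scores, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    return PCAResult(scores=frame, explained=explained, n_components=n_components)


def pca_of_genotypes(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    res = pca(grm(gm), n_components=n_components)
    res.scores.insert(0, "sample_id", gm.sample_ids)
    return res


def plot_pca(
    result: PCAResult,
    path,
    color_by: dict[str, str] | None = None,
    components: tuple[int, int] = (1, 2),
) -> None:
    """Optional static scatter of two components, colored by a sample ->
    label mapping (pack, region, platform...)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cx, cy = f"PC{components[0]}", f"PC{components[1]}"
    fig, ax = plt.subplots(figsize=(6, 5))
    sids = result.scores.get("sample_id")
    labels = (
        [color_by.get(s, "?") for s in sids]
        if (color_by is not None and sids is not None)
        else ["all"] * len(result.scores)
    )
    for lab in dict.fromkeys(labels):
        m = [l == lab for l in labels]
        ax.scatter(
            result.scores.loc[m, cx], result.scores.loc[m, cy], s=18, label=lab
        )
    ax.set_xlabel(f"{cx} ({100 * result.explained[components[0] - 1]:.1f}%)")
    ax.set_ylabel(f"{cy} ({100 * result.explained[components[1] - 1]:.1f}%)")
    if color_by is not None and len(dict.fromkeys(labels)) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
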
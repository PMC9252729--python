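"""Static rendering of the nine plot kinds.

histogram, kernel-density, heatmap, boxplot, line chart, scatter,
circular correlation plot, 3-D backbone trace and 2-D ligand depiction,
written as PNG/JPG/PDF/TIFF files via matplotlib.  Rendering never
mutates its input.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .records import FeatureMatrix  # noqa: E402

PLOT_KINDS = [
    "histogram", "kde", "heatmap", "boxplot", "line", "scatter",
    "circular", "structure3d", "ligand2d",
]
IMAGE_FORMATS = ["png", "jpg", "pdf", "tiff"]


def _by_label(matrix: FeatureMatrix) -> dict[str, np.ndarray]:
    """Flattened values grouped by sample label (one group if unlabelled)."""
    x = matrix.values
    if matrix.labels is None:
        return {"all": x.ravel()}
    out: dict[str, np.ndarray] = {}
    for lab in sorted(set(matrix.labels)):
        rows = [i for i, l in enumerate(matrix.labels) if l == lab]
        out[lab] = x[rows].ravel()
    return out


def _fd_bins(data: np.ndarray, floor: int = 10) -> int:
    """Freedman-Diaconis bin count with a floor."""
    data = data[np.isfinite(data)]
    if data.size < 2:
        return floor
    q75, q25 = np.percentile(data, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return floor
    width = 2 * iqr / data.size ** (1 / 3)
    span = data.max() - data.min()
    if width <= 0 or span <= 0:
        return floor
    return max(floor, int(np.ceil(span / width)))


def _hist(ax, matrix: FeatureMatrix, options) -> None:
    groups = _by_label(matrix)
    bins = _fd_bins(matrix.values.ravel())
    for lab, vals in groups.items():
        ax.hist(vals, bins=bins, alpha=0.6, label=lab)
    if len(groups) > 1:
        ax.legend()
    ax.set_xlabel("feature value")
    ax.set_ylabel("count")


def _kde(ax, matrix: FeatureMatrix, options) -> None:
    from scipy.stats import gaussian_kde

    for lab, vals in _by_label(matrix).items():
        vals = vals[np.isfinite(vals)]
        if vals.size < 2 or np.std(vals) == 0:
            ax.axvline(vals[0] if vals.size else 0.0, label=lab)
            continue
        kde = gaussian_kde(vals, bw_method="scott")
        grid = np.linspace(vals.min(), vals.max(), 256)
        ax.plot(grid, kde(grid), label=lab)
    ax.legend()
    ax.set_xlabel("feature value")
    ax.set_ylabel("density")


def _heatmap(ax, matrix: FeatureMatrix, options) -> None:
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xlabel("features")
    ax.set_ylabel("samples")
    plt.colorbar(im, ax=ax)


def _boxplot(ax, matrix: FeatureMatrix, options) -> None:
    cols = matrix.values
    max_cols = int(options.get("max_features", 30))
    names = matrix.feature_names[:max_cols]
    ax.boxplot([cols[:, i] for i in range(len(names))], tick_labels=names)
    ax.tick_params(axis="x", rotation=90)


def _line(ax, matrix: FeatureMatrix, options) -> None:
    for i, sid in enumerate(matrix.sample_ids):
        ax.plot(matrix.values[i], label=sid)
    if len(matrix.sample_ids) <= 10:
        ax.legend()
    ax.set_xlabel("feature index")
    ax.set_ylabel("value")


def _scatter(ax, matrix: FeatureMatrix, options) -> None:
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("scatter needs a 2-D embedding")
    colors = options.get("cluster_ids")
    if colors is None and matrix.labels is not None:
        classes = sorted(set(matrix.labels))
        colors = [classes.index(l) for l in matrix.labels]
    sc = ax.scatter(x[:, 0], x[:, 1], c=colors, cmap="tab10")
    if colors is not None:
        plt.colorbar(sc, ax=ax)
    ax.set_xlabel(matrix.feature_names[0])
    ax.set_ylabel(matrix.feature_names[1])


def correlation_edges(
    matrix: FeatureMatrix, metric: str = "pearson", threshold: float = 0.75
) -> list[tuple[int, int]]:
    """Sample pairs whose similarity reaches the threshold.

    Pearson correlation by default; cosine similarity and a
    1/(1+distance) Euclidean similarity are offered as alternatives.
    """
    x = matrix.values
    n = x.shape[0]
    if metric == "pearson":
        with np.errstate(invalid="ignore"):
            sim = np.corrcoef(x)
        sim = np.nan_to_num(sim)
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        sim = (x / norms) @ (x / norms).T
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        sim = 1.0 / (1.0 + d)
    else:
        raise ValueError(f"unknown circular metric {metric!r}")
    return [
        (i, j) for i in range(n) for j in range(i + 1, n)
        if sim[i, j] >= threshold
    ]


def _circular(ax, matrix: FeatureMatrix, options) -> None:
    """Samples on a rim, edges where pairwise correlation passes the
    threshold (Pearson by default; euclidean/cosine similarity options)."""
    n = matrix.shape[0]
    edges = correlation_edges(
        matrix,
        options.get("metric", "pearson"),
        float(options.get("threshold", 0.75)),
    )
    theta = 2 * np.pi * np.arange(n) / max(1, n)
    px, py = np.cos(theta), np.sin(theta)
    for i, j in edges:
        ax.plot([px[i], px[j]], [py[i], py[j]], color="steelblue",
                alpha=0.6, lw=0.8)
    ax.scatter(px, py, zorder=3, color="darkorange")
    for i, sid in enumerate(matrix.sample_ids):
        ax.annotate(sid, (px[i] * 1.08, py[i] * 1.08), fontsize=6,
                    ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")


def _structure3d(fig, model, options) -> None:
    ax = fig.add_subplot(projection="3d")
    cas = np.array([r.ca for r in model.residues if r.ca is not None])
    ax.plot(cas[:, 0], cas[:, 1], cas[:, 2], "-o", ms=3)
    ax.set_title("backbone trace")


def _ligand2d(ax, mol, options) -> None:
    from rdkit.Chem import AllChem

    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    pos = np.array([
        [conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
        for i in range(mol.GetNumAtoms())
    ])
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        lw = 2.5 if bond.GetBondTypeAsDouble() > 1 else 1.2
        ax.plot(pos[[i, j], 0], pos[[i, j], 1], color="black", lw=lw)
    for i, atom in enumerate(mol.GetAtoms()):
        if atom.GetSymbol() != "C":
            ax.annotate(atom.GetSymbol(), pos[i], ha="center", va="center",
                        fontsize=10, color="firebrick",
                        bbox=dict(boxstyle="circle", fc="white", ec="none"))
    ax.set_aspect("equal")
    ax.axis("off")


def render(data, kind: str, path: str, options: dict | None = None) -> str:
    """Render one plot kind to ``path`` (format from the file suffix,
    one of png/jpg/pdf/tiff).  Returns the path written."""
    options = dict(options or {})
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}")
    suffix = path.rsplit(".", 1)[-1].lower()
    if suffix not in IMAGE_FORMATS + ["jpeg", "tif"]:
        raise ValueError(f"unsupported image format {suffix!r}")
    fig = plt.figure(figsize=options.get("figsize", (6, 5)))
    try:
        if kind == "structure3d":
            _structure3d(fig, data, options)
        else:
            ax = fig.add_subplot()
            if kind == "ligand2d":
                _ligand2d(ax, data, options)
            else:
                if not isinstance(data, FeatureMatrix):
                    raise ValueError(f"{kind} plot needs a FeatureMatrix")
                if data.values.size == 0:
                    raise ValueError("empty matrix")
                {
                    "histogram": _hist,
                    "kde": _kde,
                    "heatmap": _heatmap,
                    "boxplot": _boxplot,
                    "line": _line,
                    "scatter": _scatter,
                    "circular": _circular,
                }[kind](ax, data, options)
        fig.tight_layout()
        fig.savefig(path)
    finally:
        plt.close(fig)
    return path
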
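"""Statistical comparison of mutation spectra.

The analyses here quantify how mutation spectra co-vary across samples,
species and genomic compartments: PCA of centered/scaled spectrum
matrices, NMF signature extraction with cross-run agglomerative
clustering, within/between-group Euclidean distance distributions,
per-class log-odds heatmaps between compartments and their cross-species
Pearson correlation, a multinomial log-likelihood test of how well a de
novo mutation spectrum fits candidate species spectra, and a bootstrap
enrichment test of a single class against length-matched null
compartments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, cdist, squareform
from scipy.stats import pearsonr
from sklearn.decomposition import PCA, NMF

from .normalize import RescaledRates, downscale_counts
from .spectra import SpectrumVector

# --------------------------------------------------------------------------
# spectrum matrices and PCA
# --------------------------------------------------------------------------


def build_spectrum_matrix(
    spectra: "list[SpectrumVector] | list[RescaledRates]",
) -> pd.DataFrame:
    """Stack spectra/rate vectors into a rows-by-classes matrix.

    Row labels carry provenance (``id|compartment``); all inputs must
    share the class order and unit.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    rows, labels = [], []
    units = set()
    for i, s in enumerate(spectra):
        if isinstance(s, RescaledRates):
            rows.append(s.rates)
            labels.append(f"{s.compartment}|row{i}")
            units.add("rate")
        else:
            rows.append(s.values)
            name = s.provenance.get("id", f"row{i}")
            comp = s.provenance.get("compartment", "")
            labels.append(f"{name}|{comp}" if comp else name)
            units.add(s.unit)
    if len(units) > 1:
        raise ValueError(f"mixed units in spectrum matrix: {sorted(units)}")
    mat = np.vstack(rows)
    from . import catalog

    order = 3 if mat.shape[1] == len(catalog.classes(3)) else 7
    return pd.DataFrame(mat, index=labels, columns=list(catalog.classes(order)))


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame           # rows = input rows, cols = PC1..
    loadings: pd.DataFrame         # rows = PCs, cols = classes
    variance_fractions: np.ndarray
    dropped_columns: list[str]

    def __post_init__(self) -> None:
        if np.any(self.variance_fractions < 0) or self.variance_fractions.sum() > 1 + 1e-9:
            raise ValueError("invalid variance fractions")


def run_pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of a spectrum matrix, centered and scaled by default.

    Zero-variance columns are dropped before scaling.  Components are
    ordered by decreasing variance, and each loading vector is oriented
    so its largest-magnitude entry is positive, making signs
    deterministic.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    X = matrix.to_numpy(dtype=float)
    # detect constant columns on the centered matrix; a relative threshold
    # guards against spurious ~1e-17 std from non-representable constants
    centered = X - X.mean(axis=0)
    std = centered.std(axis=0, ddof=1)
    tol = 1e-12 * max(1.0, float(np.abs(X).max()))
    keep = std > tol if scale else np.ones(X.shape[1], dtype=bool)
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    X = (centered if center else X)[:, keep]
    if scale:
        X = X / centered[:, keep].std(axis=0, ddof=1)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|entry| of each loading positive
    flip = np.sign(loadings[np.arange(n_comp), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    pcs = [f"PC{i + 1}" for i in range(n_comp)]
    cols = [c for c, k in zip(matrix.columns, keep) if k]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=pcs, columns=cols),
        variance_fractions=pca.explained_variance_ratio_.copy(),
        dropped_columns=dropped,
    )


# --------------------------------------------------------------------------
# NMF signatures
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SignatureSet:
    """NMF factorization: signatures (rows sum to 1) and exposures."""

    signatures: pd.DataFrame  # K x classes, rows sum to 1
    exposures: pd.DataFrame   # rows x K
    residual: float

    @property
    def rank(self) -> int:
        return self.signatures.shape[0]


def run_nmf(
    matrix: pd.DataFrame,
    k: int,
    restarts: int = 20,
    rng: np.random.Generator | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> SignatureSet:
    """Best-of-restarts NMF (Frobenius objective, random init).

    Signature rows are normalized to sum to 1 with the mass moved into
    the exposures, so exposures are in units of (rescaled) mutation
    counts.
    """
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    if not (0 < k < min(X.shape[0], X.shape[1]) + 1):
        raise ValueError(f"invalid NMF rank {k}")
    rng = rng if rng is not None else np.random.default_rng()
    best = None
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for _ in range(max(restarts, 1)):
        seed = int(rng.integers(2**31 - 1))
        model = NMF(
            n_components=k, init="random", solver="cd", beta_loss="frobenius",
            max_iter=max_iter, random_state=seed, tol=tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    err, W, H = best
    mass = H.sum(axis=1)
    mass[mass == 0] = 1.0
    H = H / mass[:, None]
    W = W * mass[None, :]
    sig_names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        signatures=pd.DataFrame(H, index=sig_names, columns=matrix.columns),
        exposures=pd.DataFrame(W, index=matrix.index, columns=sig_names),
        residual=float(err),
    )


def match_signatures(
    inferred: pd.DataFrame, truth: np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy cosine matching of inferred signatures to ground-truth rows.

    Returns (truth row, inferred row, cosine similarity) triples, best
    matches first, each row used at most once.
    """
    A = np.asarray(truth, dtype=float)
    B = inferred.to_numpy(dtype=float)
    sim = 1 - cdist(A, B, metric="cosine")
    pairs = []
    used_t, used_i = set(), set()
    for _ in range(min(A.shape[0], B.shape[0])):
        masked = sim.copy()
        for t in used_t:
            masked[t, :] = -np.inf
        for i in used_i:
            masked[:, i] = -np.inf
        t, i = np.unravel_index(np.argmax(masked), masked.shape)
        pairs.append((int(t), int(i), float(sim[t, i])))
        used_t.add(int(t))
        used_i.add(int(i))
    return pairs


def cluster_signatures(
    signature_sets: list[SignatureSet],
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
) -> pd.DataFrame:
    """Agglomerative clustering of signatures pooled across runs.

    Cosine distance with average linkage; cut either at a cluster count
    or a distance threshold.  Returns a table (run, signature, cluster).
    """
    rows, meta = [], []
    for run_i, ss in enumerate(signature_sets):
        for name, row in ss.signatures.iterrows():
            rows.append(row.to_numpy())
            meta.append((run_i, name))
    if len(rows) < 2:
        raise ValueError("need at least two signatures to cluster")
    X = np.vstack(rows)
    if len({r.shape[0] for r in rows}) > 1:
        raise ValueError("inconsistent signature dimensionality")
    d = pdist(X, metric="cosine")
    Z = average(d)
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif distance_threshold is not None:
        labels = fcluster(Z, t=distance_threshold, criterion="distance")
    else:
        raise ValueError("specify n_clusters or distance_threshold")
    return pd.DataFrame(
        {"run": [m[0] for m in meta], "signature": [m[1] for m in meta], "cluster": labels}
    )


# --------------------------------------------------------------------------
# Euclidean distance distributions
# --------------------------------------------------------------------------


def pairwise_distance_distributions(
    spectra: list[SpectrumVector],
    group_of: dict[str, str],
    use_frequencies: bool = True,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Within- and between-group Euclidean distances of individual spectra.

    Returns ({group: C(k,2) distances}, {(group_a, group_b): k*l
    distances}).  Frequencies are compared by default (a counts option
    is provided, since total variant numbers differ between samples).
    """
    ids = [s.provenance.get("id") for s in spectra]
    if use_frequencies:
        vals = np.vstack([s.frequencies().values for s in spectra])
    else:
        vals = np.vstack([s.values for s in spectra])
    groups = sorted({group_of[i] for i in ids})
    idx = {g: [j for j, i in enumerate(ids) if group_of[i] == g] for g in groups}
    within = {}
    for g in groups:
        within[g] = pdist(vals[idx[g]]) if len(idx[g]) > 1 else np.array([])
    between = {}
    for a_i, a in enumerate(groups):
        for b in groups[a_i + 1 :]:
            between[(a, b)] = cdist(vals[idx[a]], vals[idx[b]]).ravel()
    return within, between


# --------------------------------------------------------------------------
# log-odds heatmaps
# --------------------------------------------------------------------------


@dataclasses.dataclass
class LogOddsHeatmap:
    """Per-class natural-log ratio of rescaled rates between compartments.

    Classes where either rate is zero are masked (NaN); the map negates
    under swapping the two compartments.
    """

    values: np.ndarray  # NaN = masked
    compartments: tuple[str, str]
    species: str = ""

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


def log_odds_heatmap(
    rates_1: RescaledRates, rates_2: RescaledRates, species: str = ""
) -> LogOddsHeatmap:
    if rates_1.order != rates_2.order:
        raise ValueError("rate vectors on different class sets")
    r1, r2 = rates_1.rates, rates_2.rates
    out = np.full(len(r1), np.nan)
    ok = (r1 > 0) & (r2 > 0)
    out[ok] = np.log(r1[ok] / r2[ok])
    return LogOddsHeatmap(out, (rates_1.compartment, rates_2.compartment), species)


def heatmap_correlation(h1: LogOddsHeatmap, h2: LogOddsHeatmap) -> tuple[float, float]:
    """Pearson correlation of two heatmaps over jointly unmasked classes."""
    if h1.values.shape != h2.values.shape:
        raise ValueError("heatmaps on different class sets")
    ok = ~(h1.mask | h2.mask)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly unmasked classes")
    r, p = pearsonr(h1.values[ok], h2.values[ok])
    return float(r), float(p)


# --------------------------------------------------------------------------
# multinomial likelihood fit of DNM spectra
# --------------------------------------------------------------------------


@dataclasses.dataclass
class LikelihoodFitResult:
    log_likelihoods: dict[str, float]
    fold_range: float
    best_species: str
    significant: bool
    threshold: float

    def __post_init__(self) -> None:
        if self.fold_range < 1 and np.isfinite(self.fold_range):
            raise ValueError("fold range must be >= 1")


FOLD_RANGE_THRESHOLD = 20.0  # fold-range analogue of alpha = 0.05


def dnm_fit_test(
    observed_counts: np.ndarray,
    species_spectra: dict[str, SpectrumVector],
    threshold: float = FOLD_RANGE_THRESHOLD,
) -> LikelihoodFitResult:
    """How well does an observed mutation-count spectrum fit each species?

    For each candidate species s with class probabilities p_i,s (its
    spectrum frequencies), the multinomial log-likelihood (constant
    coefficient omitted) is sum_i count_i * log p_i,s.  The effect size
    is the fold range exp(max - min) across species; a fold range of 20
    plays the role of a 0.05 significance cutoff.  A species with zero
    probability on an observed class scores -inf and is flagged by an
    infinite fold range.
    """
    observed_counts = np.asarray(observed_counts, dtype=float)
    if len(species_spectra) < 2:
        raise ValueError("need at least two candidate species")
    lls = {}
    obs_nz = observed_counts > 0
    for name, spec in species_spectra.items():
        p = spec.frequencies().values
        if np.any(p[obs_nz] == 0):
            lls[name] = -np.inf
            continue
        lls[name] = float(observed_counts[obs_nz] @ np.log(p[obs_nz]))
    vals = np.array(list(lls.values()))
    delta = vals.max() - vals.min()
    fold = float(np.exp(delta)) if delta < 700 else float("inf")
    best = max(lls, key=lls.get)
    return LikelihoodFitResult(
        log_likelihoods=lls,
        fold_range=fold,
        best_species=best,
        significant=fold >= threshold,
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# bootstrap enrichment test
# --------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapEnrichmentResult:
    observed: float
    ci_low: float
    ci_high: float
    null_values: np.ndarray
    outside_null: bool
    class_index: int


def _class_log_odds(
    target: SpectrumVector,
    background: SpectrumVector,
    target_content,
    background_content,
    class_index: int,
) -> float:
    """Log odds of one class between two downscale-normalized spectra."""
    adj_t, adj_b = downscale_counts(target, target_content, background, background_content)
    ft = adj_t.values[class_index] / adj_t.values.sum()
    fb = adj_b.values[class_index] / adj_b.values.sum()
    if ft == 0 or fb == 0:
        return np.nan
    return float(np.log(ft / fb))


def bootstrap_enrichment_test(
    target: SpectrumVector,
    background: SpectrumVector,
    target_content,
    background_content,
    class_index: int,
    replicate_spectra: list[SpectrumVector],
    replicate_contents: list,
    rng: np.random.Generator,
    n_boot_ci: int = 1000,
) -> BootstrapEnrichmentResult:
    """Is one class enriched in the target beyond compartment-shape effects?

    The observed statistic is the class's log odds between the target and
    background spectra after pairwise count downscaling.  The null
    distribution repeats the statistic for each length-matched replicate
    compartment (spectra and contents recomputed per replicate).  A 95%
    percentile CI on the observed value comes from multinomial
    resampling of the target's variants.  The enrichment is flagged when
    the observed value lies outside the empirical min-max of the null.
    """
    if len(replicate_spectra) != len(replicate_contents):
        raise ValueError("replicate spectra and contents differ in length")
    observed = _class_log_odds(
        target, background, target_content, background_content, class_index
    )
    n = int(round(target.total))
    p = target.values / target.total
    boots = np.empty(n_boot_ci)
    for b in range(n_boot_ci):
        resampled = SpectrumVector(
            rng.multinomial(n, p).astype(float), target.order, "count",
            dict(target.provenance),
        )
        boots[b] = _class_log_odds(
            resampled, background, target_content, background_content, class_index
        )
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    null_values = np.array(
        [
            _class_log_odds(spec, background, cont, background_content, class_index)
            for spec, cont in zip(replicate_spectra, replicate_contents)
        ]
    )
    finite_null = null_values[np.isfinite(null_values)]
    outside = bool(observed < finite_null.min() or observed > finite_null.max())
    return BootstrapEnrichmentResult(
        observed=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        null_values=null_values,
        outside_null=outside,
        class_index=class_index,
    )


# --------------------------------------------------------------------------
# plotting hooks (no analysis depends on these)
# --------------------------------------------------------------------------


def plot_pca(result: PCAResult, labels: dict[str, str] | None = None, path=None):
    """Scatter of PC1/PC2 colored by a row-label grouping."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = result.scores["PC1"]
    ys = result.scores["PC2"] if "PC2" in result.scores else xs * 0
    if labels:
        groups = sorted(set(labels.values()))
        for g in groups:
            rows = [i for i in result.scores.index if labels.get(str(i).split("|")[0]) == g]
            ax.scatter(xs.loc[rows], ys.loc[rows], label=g, s=18)
        ax.legend(fontsize=7)
    else:
        ax.scatter(xs, ys, s=18)
    vf = result.variance_fractions
    ax.set_xlabel(f"PC1 ({vf[0]:.1%})")
    if len(vf) > 1:
        ax.set_ylabel(f"PC2 ({vf[1]:.1%})")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_log_odds_heatmap(heatmap: LogOddsHeatmap, path=None):
    """96-class log-odds grid (6 substitution types x 16 flank pairs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = heatmap.values.reshape(6, 16, order="F") if heatmap.values.size == 96 else None
    fig, ax = plt.subplots(figsize=(8, 3))
    data = grid if grid is not None else heatmap.values[None, :]
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    fig.colorbar(im, ax=ax, label="ln rate ratio")
    ax.set_title(f"{heatmap.compartments[0]} vs {heatmap.compartments[1]} {heatmap.species}")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
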
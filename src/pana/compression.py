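"""Pathway compression: bootstrap-thresholded PCA per pathway.

Each pathway's expression submatrix is reduced to a small number of
*pathway profiles* — principal-component score vectors that summarise the
coordinated expression changes of the pathway's genes across samples.
Component significance is judged against the genome-wide gene-variance
distribution: in each bootstrap repetition the sample columns are
resampled with replacement, a gamma distribution is fitted to the per-gene
variances of the resampled full matrix, and its upper ``1 - alpha``
quantile becomes the eigenvalue cutoff for that repetition. A component
rank is retained when it clears the cutoff in more than a fraction ``Q``
of repetitions. Final scores and loadings come from a single PCA of the
original (un-resampled) submatrix.

Within one repetition the same resampled column index vector is used both
for the genome-wide cutoff and for the pathway submatrix PCA, keeping the
cutoff and the eigenvalues on the same resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PathwayAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CompressionParams",
    "Profile",
    "ProfileSet",
    "variance_cutoff",
    "fit_gamma_cutoff",
    "select_components",
    "build_plm",
]


@dataclass
class CompressionParams:
    """Tuning knobs for profile extraction.

    alpha        significance level of the gamma variance cutoff (smaller
                 alpha -> higher cutoff -> fewer components retained)
    n_boot       bootstrap repetitions R
    q_threshold  selection-frequency threshold Q; a component rank must
                 clear the cutoff in a fraction > Q of repetitions
    gamma_method 'mle' (default) or 'moments' gamma fit
    """

    alpha: float = 0.05
    n_boot: int = 100
    q_threshold: float = 0.95
    seed: int = 0
    gamma_method: str = "mle"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.gamma_method not in ("mle", "moments"):
            raise ValueError("gamma_method must be 'mle' or 'moments'")


@dataclass
class Profile:
    """One retained pathway profile (a principal-component score vector)."""

    pathway_id: str
    component_index: int          # 1-based PC rank within the pathway
    scores: np.ndarray            # length M, zero mean
    gene_ids: list[str]           # pathway genes, matrix row order
    loadings: np.ndarray          # length N_f, unit Euclidean norm
    eigenvalue: float

    @property
    def profile_id(self) -> str:
        return f"{self.pathway_id}#{self.component_index}"


@dataclass
class ProfileSet:
    """All retained profiles plus the Pathway Level Matrix (PLM).

    The PLM is the row-wise concatenation of the retained score vectors:
    pathways in annotation order, components in ascending rank.
    """

    profiles: list[Profile]
    sample_ids: list[str]
    #: pathway_id -> (h_f, {component rank i: selection frequency of >= i})
    selection: dict[str, tuple[int, dict[int, float]]] = field(default_factory=dict)
    params: CompressionParams | None = None

    @property
    def plm(self) -> np.ndarray:
        return np.vstack([p.scores for p in self.profiles])

    @property
    def profile_ids(self) -> list[str]:
        return [p.profile_id for p in self.profiles]

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def get(self, profile_id: str) -> Profile:
        for p in self.profiles:
            if p.profile_id == profile_id:
                return p
        raise KeyError(profile_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.plm, index=self.profile_ids, columns=self.sample_ids)

    def write_plm(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="profile_id")

    def write_loadings(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("profile_id\tgene_id\tloading\n")
            for p in self.profiles:
                for g, w in zip(p.gene_ids, p.loadings):
                    fh.write(f"{p.profile_id}\t{g}\t{w:.10g}\n")

    def write_selection_report(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pathway_id\th_f\tcomponent\tfrequency\n")
            for pid, (h, freqs) in self.selection.items():
                if not freqs:
                    fh.write(f"{pid}\t{h}\t-\t-\n")
                for i in sorted(freqs):
                    fh.write(f"{pid}\t{h}\t{i}\t{freqs[i]:.4f}\n")


# ---------------------------------------------------------------------------
# gamma variance cutoff


def fit_gamma_cutoff(variances: np.ndarray, alpha: float, method: str) -> float:
    """Fit a gamma distribution to per-gene variances; return its 1-alpha quantile."""
    v = np.asarray(variances, dtype=float)
    v = v[v > 0]
    if v.size == 0 or v.max() <= 0:
        raise ValueError("degenerate gamma fit: all gene variances are zero")
    if method == "moments":
        m, s2 = v.mean(), v.var()
        if s2 <= 0:
            raise ValueError("degenerate gamma fit: zero-variance variance sample")
        shape = m * m / s2
        scale = s2 / m
    else:
        shape, _, scale = stats.gamma.fit(v, floc=0)
    return float(stats.gamma.ppf(1.0 - alpha, shape, scale=scale))


def variance_cutoff(matrix: ExpressionMatrix, alpha: float,
                    rng: np.random.Generator, method: str = "mle") -> float:
    """One bootstrap draw of the genome-wide variance cutoff.

    Resamples the sample columns with replacement, computes per-gene
    variances, fits a gamma distribution and returns its ``1 - alpha``
    quantile.
    """
    idx = rng.integers(0, matrix.n_samples, matrix.n_samples)
    variances = matrix.values[:, idx].var(axis=1, ddof=1)
    return fit_gamma_cutoff(variances, alpha, method)


# ---------------------------------------------------------------------------
# PCA helpers


def _centered_samples_by_genes(sub: np.ndarray) -> np.ndarray:
    """Transpose a genes x samples block and centre each gene column."""
    a = sub.T
    return a - a.mean(axis=0, keepdims=True)


def _eigenvalues(sub: np.ndarray) -> np.ndarray:
    """PCA eigenvalues (descending) of a genes x samples block.

    Computed from the M x M Gram matrix of the centred samples-by-genes
    matrix; eigenvalues equal squared singular values / (M - 1).
    """
    a = _centered_samples_by_genes(sub)
    m = a.shape[0]
    g = a @ a.T
    w = np.linalg.eigvalsh(g)[::-1]
    w = np.clip(w, 0.0, None) / (m - 1)
    return w


def _bootstrap_counts(full: np.ndarray, subs: list[np.ndarray],
                      params: CompressionParams) -> np.ndarray:
    """Selected-component counts k(r) per repetition (R x n_pathways)."""
    n, m = full.shape
    rng = np.random.default_rng(params.seed)
    counts = np.zeros((params.n_boot, len(subs)), dtype=int)
    for r in range(params.n_boot):
        idx = rng.integers(0, m, m)
        variances = full[:, idx].var(axis=1, ddof=1)
        cutoff = fit_gamma_cutoff(variances, params.alpha, params.gamma_method)
        for p, sub in enumerate(subs):
            if sub.shape[0] < 2:
                continue
            w = _eigenvalues(sub[:, idx])
            counts[r, p] = int((w > cutoff).sum())
    return counts


def _h_from_counts(counts: np.ndarray, q: float) -> tuple[int, dict[int, float]]:
    """Largest rank selected with frequency > Q, plus the frequency table.

    Within each repetition the selected component indices form the prefix
    1..k(r) (eigenvalues are ordered), so the frequency of rank ``i`` is
    the fraction of repetitions with k(r) >= i.
    """
    kmax = int(counts.max(initial=0))
    freqs = {i: float((counts >= i).mean()) for i in range(1, kmax + 1)}
    h = 0
    for i in range(1, kmax + 1):
        if freqs[i] > q:
            h = i
        else:
            break
    return h, freqs


def select_components(submatrix: np.ndarray, params: CompressionParams,
                      full_matrix: ExpressionMatrix) -> tuple[int, dict[int, float]]:
    """Number of significant components h_f for one pathway block.

    ``submatrix`` is the pathway's genes x samples block; the genome-wide
    variance cutoff is recomputed per repetition from ``full_matrix`` on
    the same resampled columns. Pathways with fewer than 2 genes yield
    h_f = 0.
    """
    sub = np.asarray(submatrix, dtype=float)
    if sub.shape[0] < 2:
        return 0, {}
    counts = _bootstrap_counts(full_matrix.values, [sub], params)
    return _h_from_counts(counts[:, 0], params.q_threshold)


def _final_pca(sub: np.ndarray, h: int):
    """Scores, loadings and eigenvalues of the top ``h`` components.

    Signs follow a fixed convention: each component is flipped so that its
    largest-magnitude loading is positive.
    """
    a = _centered_samples_by_genes(sub)
    m = a.shape[0]
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    scores = u[:, :h] * s[:h]
    loadings = vt[:h].T
    eig = (s[:h] ** 2) / (m - 1)
    for j in range(h):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, eig


def build_plm(matrix: ExpressionMatrix, annotation: PathwayAnnotation,
              params: CompressionParams) -> ProfileSet:
    """Run compression for every pathway and assemble the PLM.

    Pathways whose genes are absent from the matrix are reduced to their
    measured genes; pathways with < 2 measured genes or h_f = 0 are
    excluded from the PLM (recorded in ``selection``).
    """
    pids = list(annotation.pathways)
    gene_lists = {pid: matrix.genes_present(annotation[pid]) for pid in pids}
    n_unmeasured = sum(len(annotation[pid]) - len(gene_lists[pid]) for pid in pids)
    if n_unmeasured:
        logger.info("%d annotated genes not present in the expression matrix "
                    "were ignored", n_unmeasured)
    subs = [matrix.submatrix(gene_lists[pid]) for pid in pids]
    counts = _bootstrap_counts(matrix.values, subs, params)

    profiles: list[Profile] = []
    selection: dict[str, tuple[int, dict[int, float]]] = {}
    for p, pid in enumerate(pids):
        h, freqs = _h_from_counts(counts[:, p], params.q_threshold)
        selection[pid] = (h, freqs)
        if h < 1:
            continue
        scores, loadings, eig = _final_pca(subs[p], h)
        for j in range(h):
            profiles.append(Profile(
                pathway_id=pid,
                component_index=j + 1,
                scores=scores[:, j].copy(),
                gene_ids=gene_lists[pid],
                loadings=loadings[:, j].copy(),
                eigenvalue=float(eig[j]),
            ))
    if not profiles:
        raise ValueError(
            "empty PLM: no pathway retained a significant profile; "
            "consider a larger alpha")
    return ProfileSet(profiles, list(matrix.sample_ids), selection, params)


def read_plm(path) -> ProfileSet:
    """Read a PLM TSV back into a (scores-only) ProfileSet.

    Loadings and eigenvalues are not stored in the PLM file; profiles are
    reconstructed with empty gene/loading vectors, which is sufficient for
    rule inference and network assembly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = []
    for rid, row in zip(df.index.astype(str), df.to_numpy(dtype=float)):
        if "#" not in rid:
            raise ValueError(f"{path}: profile id {rid!r} lacks '#component' suffix")
        pid, comp = rid.rsplit("#", 1)
        profiles.append(Profile(pid, int(comp), row, [], np.empty(0), float("nan")))
    return ProfileSet(profiles, list(df.columns.astype(str)))
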
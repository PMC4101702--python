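"""Association-rule inference between pathway profiles.

For each target profile the PLM is discretized into high/low activity
states (+1/-1): the target row at its own mean, every other row at the
threshold that minimises the *partition entropy* — the weighted binary
entropy of the target's states within the two sample subsets induced by
the candidate threshold. Candidate thresholds are the observed score
values of the source row; a sample with score <= t goes to the low
partition. Each ordered profile pair is then scored as a *direct* rule
(source state predicts the same target state) and an *opposite* rule
(source predicts the inverted state); the better class is kept and rules
whose accuracy — sensitivity x specificity of the prediction — clears a
threshold survive to network construction. Profiles of the same pathway
never form rules with each other: they are orthogonal by construction and
any association between them would be an artefact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compression import ProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRule",
    "DiscretizedPLM",
    "partition_entropy",
    "discretize",
    "infer_rules",
    "rules_to_tsv",
    "read_rules",
]


@dataclass
class AssociationRule:
    """A directed association between two pathway profiles."""

    source: str
    target: str
    rule_class: str               # 'direct' | 'opposite'
    threshold: float              # t_lj used to discretize the source row
    accuracy: float               # sensitivity * specificity
    sensitivity: float
    specificity: float
    correlation: float            # Pearson r of the continuous profiles


@dataclass
class DiscretizedPLM:
    """Discretization of the PLM relative to one target profile."""

    target_profile: str
    profile_ids: list[str]        # rows with a valid discretization
    states: np.ndarray            # len(profile_ids) x M, values in {-1, +1}
    thresholds: dict[str, float]  # source profile id -> t_lj


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (base 2) of a Bernoulli(p), with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return out


def partition_entropy(states_l, states_j) -> float:
    """Weighted entropy of ``states_j`` within the partitions of ``states_l``.

    Both vectors hold +/-1 states of equal length. The two partitions are
    the samples where ``states_l`` is -1 and +1; each contributes the
    binary entropy of ``states_j`` restricted to it, weighted by its size
    fraction. 0 means the target is constant within each partition; an
    empty partition contributes 0 with weight 0.
    """
    sl = np.asarray(states_l)
    sj = np.asarray(states_j)
    if sl.shape != sj.shape or sl.size < 2:
        raise ValueError("state vectors must have equal length >= 2")
    total = 0.0
    for side in (-1, 1):
        mask = sl == side
        n = int(mask.sum())
        if n == 0:
            continue
        p = float((sj[mask] == 1).mean())
        total += (n / sl.size) * float(_binary_entropy(np.array(p)))
    return total


def _candidate_entropies(values: np.ndarray, dj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition entropy of every candidate threshold of a source row.

    ``values`` is the continuous source row, ``dj`` the boolean target
    states (True = +1). Candidates are the sorted observed values; sample
    m lands in the high partition when values[m] > t. Returns the sorted
    candidates and their entropies, vectorised over candidates.
    """
    m = values.size
    cands = np.sort(values)
    high = values[None, :] > cands[:, None]            # n_cand x M
    n1 = high.sum(axis=1)
    n0 = m - n1
    pos1 = high @ dj.astype(float)                     # target + in high side
    pos0 = dj.sum() - pos1
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, pos1 / np.maximum(n1, 1), 0.0)
        p0 = np.where(n0 > 0, pos0 / np.maximum(n0, 1), 0.0)
    ent = (n1 / m) * _binary_entropy(p1) + (n0 / m) * _binary_entropy(p0)
    return cands, ent


def discretize(plm: ProfileSet, target: str) -> DiscretizedPLM:
    """Discretize the PLM relative to target profile ``target``.

    The target row is thresholded at its mean; every other row at the
    entropy-minimising candidate drawn from its own observed values (ties
    broken toward the smallest threshold). Constant rows, and rows whose
    best threshold leaves one state empty, are excluded and logged.
    """
    ids = plm.profile_ids
    if len(ids) < 2:
        raise ValueError("PLM must contain at least 2 profiles")
    if target not in ids:
        raise KeyError(target)
    mat = plm.plm
    trow = mat[ids.index(target)]
    dj = trow > trow.mean()
    if dj.all() or not dj.any():
        raise ValueError(f"target profile {target} is constant; cannot discretize")

    kept: list[str] = []
    states_rows: list[np.ndarray] = []
    thresholds: dict[str, float] = {}
    for i, pid in enumerate(ids):
        if pid == target:
            kept.append(pid)
            states_rows.append(np.where(dj, 1, -1))
            thresholds[pid] = float(trow.mean())
            continue
        row = mat[i]
        if np.ptp(row) == 0:
            logger.warning("profile %s is constant; excluded from discretization", pid)
            continue
        cands, ent = _candidate_entropies(row, dj)
        best = int(np.argmin(ent))       # first minimum = smallest threshold
        t = float(cands[best])
        sl = row > t
        if sl.all() or not sl.any():
            logger.warning("profile %s: best threshold for target %s is degenerate; "
                           "excluded", pid, target)
            continue
        kept.append(pid)
        states_rows.append(np.where(sl, 1, -1))
        thresholds[pid] = t
    return DiscretizedPLM(target, kept, np.vstack(states_rows), thresholds)


def _rule_from_states(sl: np.ndarray, dj: np.ndarray) -> tuple[str, float, float, float]:
    """Best rule class and (accuracy, sensitivity, specificity).

    sl, dj are boolean (True = +1). Direct rules predict the target state
    equal to the source state, opposite rules predict the inverse; the
    class with the higher sensitivity x specificity wins (ties go to
    direct).
    """
    a = int((sl & dj).sum())      # source +, target +
    b = int((sl & ~dj).sum())     # source +, target -
    c = int((~sl & dj).sum())     # source -, target +
    d = int((~sl & ~dj).sum())    # source -, target -
    pos, neg = a + c, b + d
    se_dir = a / pos if pos else 0.0
    sp_dir = d / neg if neg else 0.0
    se_opp = c / pos if pos else 0.0
    sp_opp = b / neg if neg else 0.0
    acc_dir, acc_opp = se_dir * sp_dir, se_opp * sp_opp
    if acc_dir >= acc_opp:
        return "direct", acc_dir, se_dir, sp_dir
    return "opposite", acc_opp, se_opp, sp_opp


def infer_rules(plm: ProfileSet, accuracy_min: float = 0.9) -> list[AssociationRule]:
    """Infer direct/opposite association rules between all profile pairs.

    Every ordered pair (source l, target j) of profiles from *different*
    pathways is evaluated on the discretization of the PLM relative to j;
    rules with accuracy >= ``accuracy_min`` are returned.
    """
    if not 0.0 < accuracy_min <= 1.0:
        raise ValueError("accuracy_min must be in (0, 1]")
    ids = plm.profile_ids
    pathways = plm.pathway_ids
    mat = plm.plm
    rules: list[AssociationRule] = []

    # precompute, per source row, the candidate state matrix ingredients
    const = [np.ptp(mat[i]) == 0 for i in range(len(ids))]
    corr = np.corrcoef(mat) if len(ids) > 1 else np.ones((1, 1))

    for j, tgt in enumerate(ids):
        if const[j]:
            continue
        trow = mat[j]
        dj = trow > trow.mean()
        if dj.all() or not dj.any():
            continue
        for l, src in enumerate(ids):
            if l == j or const[l] or pathways[l] == pathways[j]:
                continue
            cands, ent = _candidate_entropies(mat[l], dj)
            best = int(np.argmin(ent))
            t = float(cands[best])
            sl = mat[l] > t
            if sl.all() or not sl.any():
                continue
            cls, acc, se, sp = _rule_from_states(sl, dj)
            if acc >= accuracy_min:
                rules.append(AssociationRule(
                    source=src, target=tgt, rule_class=cls, threshold=t,
                    accuracy=acc, sensitivity=se, specificity=sp,
                    correlation=float(corr[l, j]),
                ))
    return rules


def rules_to_tsv(rules: list[AssociationRule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tclass\tthreshold\tsensitivity\tspecificity"
                 "\taccuracy\tcorrelation\n")
        for r in rules:
            fh.write(f"{r.source}\t{r.target}\t{r.rule_class}\t{r.threshold:.10g}"
                     f"\t{r.sensitivity:.6f}\t{r.specificity:.6f}"
                     f"\t{r.accuracy:.6f}\t{r.correlation:.6f}\n")


def read_rules(path) -> list[AssociationRule]:
    rules: list[AssociationRule] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "class"]:
            raise ValueError(f"{path}: unexpected rules header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rules.append(AssociationRule(
                source=f[0], target=f[1], rule_class=f[2], threshold=float(f[3]),
                sensitivity=float(f[4]), specificity=float(f[5]),
                accuracy=float(f[6]), correlation=float(f[7]),
            ))
    return rules
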
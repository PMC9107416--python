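"""Permutation controls for the classification analysis.

Two nulls are built by relabelling subjects.  The *traditional* control
re-runs LOOCV on a fixed feature subset under permuted labels; its mean
accuracy should sit near the 50 % chance level.  The *feature selection
control* (FSC) re-runs the entire SFFS + SVM + LOOCV search per
permutation, so the optimism introduced by selecting features on the
same data enters the null distribution; its mean is expected above
50 %, and the excess (mean - 50) estimates the overfitting of the
experimental accuracy.

Relabelling flips exactly half (floor(n/2)) of each group, preventing a
permutation from reproducing a mostly mirror-image of the original
labelling.  P-values use the add-one permutation estimator
p = (1 + #{null CA >= experimental CA}) / (n_perm + 1), and effect
sizes are Cohen's d_z = (experimental CA - null mean) / null SD.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import SubsetResult, encode_labels, loocv, sffs

__all__ = [
    "PermutationResult",
    "half_relabel",
    "free_relabel",
    "traditional_control",
    "fsc_control",
    "permutation_pvalue",
    "cohens_dz",
    "overfitting_estimate",
    "required_permutations",
]


@dataclass(frozen=True)
class PermutationResult:
    """Summary of a permutation null CA distribution (all CAs in %)."""

    control_kind: str  # "traditional" | "fsc"
    n_perm: int
    ca_distribution: tuple[float, ...]
    mean_ca: float
    sd_ca: float
    experimental_ca: float
    p_value: float
    d_z: float
    seed: int
    overfitting_pct: float | None = None  # FSC only: mean_ca - 50

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "control_kind": self.control_kind, "n_perm": self.n_perm,
            "experimental_ca": self.experimental_ca,
            "mean_ca": self.mean_ca, "sd_ca": self.sd_ca,
            "p_value": self.p_value, "d_z": self.d_z,
            "overfitting_pct": self.overfitting_pct, "seed": self.seed,
            "ca_distribution": list(self.ca_distribution),
        }, indent=2))


def half_relabel(labels: Sequence, rng: np.random.Generator) -> np.ndarray:
    """Flip the labels of a random floor(n_g / 2) members of each group.

    With equal group sizes the per-label counts are preserved, and no
    permutation can be (close to) a full mirror image of the original.
    """
    y = encode_labels(labels)
    out = y.copy()
    for g in (0, 1):
        members = np.flatnonzero(y == g)
        if members.size < 2:
            raise ValueError(f"group {g} has fewer than 2 members")
        flip = rng.choice(members, size=members.size // 2, replace=False)
        out[flip] = 1 - g
    return out


def free_relabel(labels: Sequence, rng: np.random.Generator) -> np.ndarray:
    """Unconstrained label shuffle (classical permutation)."""
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need two groups")
    return rng.permutation(y)


def permutation_pvalue(experimental_ca: float, distribution: Sequence[float]) -> float:
    """Add-one permutation p-value: (1 + #{null >= experimental}) / (n + 1).

    Ties count against the experimental result.
    """
    dist = np.asarray(distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(dist >= experimental_ca)) / (dist.size + 1))


def cohens_dz(experimental_ca: float, mean_ca: float, sd_ca: float) -> float:
    """Standardized distance of the experimental CA from the null:
    (experimental - mean) / SD."""
    if sd_ca <= 0:
        raise ValueError("sd_ca must be positive")
    return (experimental_ca - mean_ca) / sd_ca


def overfitting_estimate(mean_ca: float) -> float:
    """Overfitting implied by a selection-aware null: the excess of its
    mean CA (in %) over the 50 % chance level.  A null search that
    reaches 80 % CA on relabelled data indicates ~30 % overfitting."""
    return mean_ca - 50.0


def required_permutations(w: float) -> int:
    """Permutations needed to resolve a CA difference of at least ``w``
    (a proportion in (0, 1]) via the proportion-estimation rule
    n = 4 / w**2, rounded up."""
    if not 0.0 < w <= 1.0:
        raise ValueError("w must lie in (0, 1]")
    return math.ceil(4.0 / w ** 2)


def _summarize(kind: str, cas: np.ndarray, experimental_ca: float,
               seed: int) -> PermutationResult:
    mean = float(cas.mean())
    if cas.size < 2:
        warnings.warn("single-permutation distribution: SD reported as 0",
                      stacklevel=3)
        sd = 0.0
    else:
        sd = float(cas.std(ddof=1))
    p = permutation_pvalue(experimental_ca, cas)
    dz = cohens_dz(experimental_ca, mean, sd) if sd > 0 else float("nan")
    return PermutationResult(
        control_kind=kind, n_perm=cas.size, ca_distribution=tuple(cas),
        mean_ca=mean, sd_ca=sd, experimental_ca=experimental_ca,
        p_value=p, d_z=dz, seed=seed,
        overfitting_pct=(mean - 50.0) if kind == "fsc" else None)


def _perm_rngs(seed: int, n_perm: int) -> list[np.random.Generator]:
    # one child stream per permutation: results do not depend on the
    # order in which permutations are executed
    return [np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(n_perm)]


def traditional_control(
    X,
    y,
    fixed_subset: Sequence[str],
    n_perm: int = 10_000,
    c_reg: float = 1.0,
    seed: int = 0,
    relabel: str = "half",
) -> PermutationResult:
    """Fixed-subset permutation null.

    Per permutation the group labels are relabelled (half-flip by
    default) and LOOCV is re-run on ``fixed_subset``; no feature
    selection happens inside the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not fixed_subset:
        raise ValueError("fixed_subset must be non-empty")
    shuffle = {"half": half_relabel, "free": free_relabel}[relabel]
    yv = encode_labels(y)
    experimental = loocv(X, yv, subset=fixed_subset, c_reg=c_reg).ca
    cas = np.empty(n_perm)
    for i, rng in enumerate(_perm_rngs(seed, n_perm)):
        yp = shuffle(yv, rng)
        cas[i] = loocv(X, yp, subset=fixed_subset, c_reg=c_reg).ca
    return _summarize("traditional", cas, experimental, seed)


def fsc_control(
    X,
    y,
    n_perm: int = 500,
    max_size: int | None = None,
    c_reg: float = 1.0,
    seed: int = 0,
    relabel: str = "half",
    experimental: SubsetResult | None = None,
) -> PermutationResult:
    """Feature selection control: the full SFFS + SVM + LOOCV search is
    repeated per relabelling and the best CA found enters the null.

    The resulting mean exceeds 50 % on pure noise (selection optimism);
    ``overfitting_pct`` = mean - 50 estimates that excess.  Pass the
    experimental SFFS result to avoid recomputing it.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    shuffle = {"half": half_relabel, "free": free_relabel}[relabel]
    yv = encode_labels(y)
    if experimental is None:
        _, experimental = sffs(X, yv, max_size=max_size, c_reg=c_reg)
    cas = np.empty(n_perm)
    for i, rng in enumerate(_perm_rngs(seed, n_perm)):
        yp = shuffle(yv, rng)
        _, best = sffs(X, yp, max_size=max_size, c_reg=c_reg)
        cas[i] = best.ca
    return _summarize("fsc", cas, experimental.ca, seed)
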
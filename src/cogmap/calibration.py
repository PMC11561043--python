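"""Similarity-threshold calibration from random ligand pairs.

The minimum similarity required to call a bound-entity/cognate pair a
match is derived empirically: random ligand pairs approximate the score
distribution of *non*-cognate pairs, the 95th percentile of each
replicate set summarizes its upper tail, and the acceptance threshold is
set a fixed margin above the mean of those percentiles. With a margin of
+0.10 on the score scale and one-decimal rounding, a mean 95th
percentile of 0.29 yields the default working threshold of 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import Molecule, parity_score
from .errors import InputError

DEFAULT_THRESHOLD = 0.4

MoleculePair = tuple[Molecule, Molecule]


@dataclass(frozen=True)
class CalibrationResult:
    """Replicate percentiles and the derived matching threshold."""

    per_set_p95: tuple[float, ...]
    mean_p95: float
    sd_p95: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "per_set_p95": list(self.per_set_p95),
            "mean_p95": self.mean_p95,
            "sd_p95": self.sd_p95,
            "threshold": self.threshold,
        }


def sample_random_pairs(
    ligands: list[Molecule],
    n_pairs: int,
    n_sets: int,
    seed: int,
) -> list[list[MoleculePair]]:
    """Draw ``n_sets`` replicate sets of ``n_pairs`` random ligand pairs.

    Pairs are drawn uniformly; the two members of a pair are always
    distinct molecules (no self-pairs), but the same pair may recur
    across draws. Fully reproducible under a fixed seed.
    """
    if len(ligands) < 2:
        raise InputError("need at least 2 ligands to form pairs")
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ligands)
    sets: list[list[MoleculePair]] = []
    for _ in range(n_sets):
        first = rng.integers(0, n, size=n_pairs)
        # second index drawn over n-1 slots and shifted past the first,
        # which excludes self-pairing without rejection sampling
        second = rng.integers(0, n - 1, size=n_pairs)
        second = np.where(second >= first, second + 1, second)
        sets.append([(ligands[i], ligands[j]) for i, j in zip(first, second)])
    return sets


def score_pair_sets(
    sets: list[list[MoleculePair]],
    timeout_s: float = 10.0,
) -> list[np.ndarray]:
    """PARITY-score every pair in every set.

    Scores are cached per unordered molecule-id pair within the call, so
    repeated pairs across replicate sets cost one MCS search.
    """
    cache: dict[tuple[str, str], float] = {}
    out = []
    for pairs in sets:
        scores = np.empty(len(pairs))
        for k, (a, b) in enumerate(pairs):
            key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
            if key not in cache:
                cache[key] = parity_score(a, b, timeout_s=timeout_s).score
            scores[k] = cache[key]
        out.append(scores)
    return out


def calibrate_threshold(
    score_sets: list[np.ndarray],
    percentile: float = 95.0,
    margin: float = 0.10,
    rounding: int = 1,
    margin_mode: str = "additive",
) -> CalibrationResult:
    """Derive the matching threshold from replicate random-pair scores.

    Per-set percentiles use linear interpolation between order
    statistics. ``margin_mode="additive"`` (default) sets
    ``threshold = round(mean_p95 + margin, rounding)``;
    ``"multiplicative"`` uses ``mean_p95 * (1 + margin)`` instead.
    """
    if not score_sets or any(len(s) == 0 for s in score_sets):
        raise InputError("every score set must be non-empty")
    p95s = tuple(
        float(np.percentile(np.asarray(s, dtype=float), percentile))
        for s in score_sets
    )
    mean_p95 = float(np.mean(p95s))
    sd_p95 = float(np.std(p95s, ddof=1)) if len(p95s) > 1 else 0.0
    if margin_mode == "additive":
        raw = mean_p95 + margin
    elif margin_mode == "multiplicative":
        raw = mean_p95 * (1.0 + margin)
    else:
        raise InputError(f"unknown margin_mode {margin_mode!r}")
    threshold = float(round(raw, rounding))
    return CalibrationResult(
        per_set_p95=p95s, mean_p95=mean_p95, sd_p95=sd_p95, threshold=threshold
    )


def calibrate_from_library(
    ligands: list[Molecule],
    n_pairs: int = 2000,
    n_sets: int = 5,
    seed: int = 0,
    timeout_s: float = 10.0,
    **kwargs,
) -> CalibrationResult:
    """End-to-end calibration: sample pairs, score, derive threshold."""
    sets = sample_random_pairs(ligands, n_pairs=n_pairs, n_sets=n_sets, seed=seed)
    return calibrate_threshold(score_pair_sets(sets, timeout_s=timeout_s), **kwargs)
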
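"""Recovery benchmarks and brute-force reference implementations.

These routines measure the pipeline against its own ground truth (phantom
recovery, simulator parameter recovery, CI calibration) and provide slow,
obviously-correct reference implementations (flood-fill component counting)
used to cross-check the production code.  They are exercised by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Optional

import numpy as np

from .cohort import CohortSpec, simulate_cohort
from .detection import DetectionParams, quantify_eye
from .phantom import VolumeSpec, generate_surfaces, render_volume, sample_interior_foci
from .stats import logistic_univariate

__all__ = [
    "flood_fill_count",
    "detection_recovery",
    "straddle_total_count",
    "or_recovery",
    "ci_coverage",
]


def flood_fill_count(binary: np.ndarray, connectivity: int = 8, min_area: int = 1) -> int:
    """Brute-force BFS connected-component count of a binary image.

    Deliberately naive (explicit queue, pixel-by-pixel) so it serves as an
    independent oracle for the production particle analysis.
    """
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    seen = np.zeros_like(binary)
    nx, ny = binary.shape
    count = 0
    for i in range(nx):
        for j in range(ny):
            if not binary[i, j] or seen[i, j]:
                continue
            area = 0
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                x, y = queue.popleft()
                area += 1
                for dx, dy in steps:
                    u, v = x + dx, y + dy
                    if 0 <= u < nx and 0 <= v < ny and binary[u, v] and not seen[u, v]:
                        seen[u, v] = True
                        queue.append((u, v))
            if area >= min_area:
                count += 1
    return count


def detection_recovery(
    n_phantoms: int = 100,
    seed: int = 0,
    speckle_shape: float = 0.0,
    n_foci_range: tuple = (2, 8),
    spec_kwargs: Optional[dict] = None,
    params: DetectionParams = DetectionParams(),
    match_radius_px: float = 3.0,
) -> dict:
    """Detect implanted foci on random phantoms and score against truth.

    Each phantom has foci strictly interior to single slabs (so truth is
    unambiguous).  Returns the fraction of phantoms whose per-slab counts
    match truth exactly, the per-(focus,slab) recall under centroid
    matching, and the worst per-slab false-positive rate per eye.
    """
    master = np.random.default_rng(seed)
    kwargs = dict(spec_kwargs or {})
    kwargs["speckle_shape"] = speckle_shape
    exact = 0
    truth_total = 0
    matched_total = 0
    fp_per_slab = np.zeros(5)
    for i in range(n_phantoms):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        spec = VolumeSpec(seed=sub, **kwargs)
        surfaces = generate_surfaces(spec)
        n_foci = int(rng.integers(*n_foci_range))
        foci = sample_interior_foci(rng, spec, surfaces, n_foci)
        volume, truth = render_volume(spec, surfaces, foci, rng=rng)
        table = quantify_eye(volume, surfaces, params)
        if np.array_equal(table.per_slab_counts(), truth.per_slab_counts()):
            exact += 1
        # centroid matching per slab
        det = table.frame
        for slab in range(1, 6):
            truths = truth.frame[truth.frame.slab == slab]
            comps = det[det.slab == slab][["centroid_x", "centroid_y"]].to_numpy()
            used = np.zeros(len(comps), dtype=bool)
            for _, t in truths.iterrows():
                truth_total += 1
                if len(comps) == 0:
                    continue
                d = np.hypot(comps[:, 0] - t.x, comps[:, 1] - t.y)
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= t.radius_px + match_radius_px:
                    used[j] = True
                    matched_total += 1
            fp_per_slab[slab - 1] += int((~used).sum())
    return {
        "n_phantoms": n_phantoms,
        "exact_match_fraction": exact / n_phantoms,
        "recall": matched_total / truth_total if truth_total else float("nan"),
        "n_truth": truth_total,
        "fp_per_eye_worst_slab": float(fp_per_slab.max() / n_phantoms),
        "fp_per_eye_by_slab": (fp_per_slab / n_phantoms).tolist(),
    }


def straddle_total_count(seed: int = 0, speckle_shape: float = 0.0) -> int:
    """Total detected count for one lesion centered on the slab 1/2 boundary."""
    spec = VolumeSpec(speckle_shape=speckle_shape, seed=seed)
    surfaces = generate_surfaces(spec)
    from .phantom import FocusSpec

    volume, _ = render_volume(
        spec, surfaces, [FocusSpec(x=64, y=16, frac_depth=0.80, radius_px=2.0)]
    )
    return int(quantify_eye(volume, surfaces).total_count)


def or_recovery(n_eyes: int = 5000, true_or: float = 2.13, seed: int = 0) -> float:
    """Univariate OR for slab 1 on a cohort simulated with that true OR."""
    spec = CohortSpec(
        n_eyes=n_eyes,
        beta_per_slab=(math.log(true_or), 0.0, 0.0, 0.0, 0.0),
        seed=seed,
    )
    res = logistic_univariate(simulate_cohort(spec), 1)
    return float(res.odds_ratio)


def ci_coverage(
    n_cohorts: int = 500,
    n_eyes: int = 300,
    true_or: float = 1.5,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts whose 95% Wald CI covers the true OR."""
    master = np.random.default_rng(seed)
    covered = 0
    fitted = 0
    for _ in range(n_cohorts):
        sub = int(master.integers(0, 2**31 - 1))
        spec = CohortSpec(
            n_eyes=n_eyes,
            beta_per_slab=(math.log(true_or), 0.0, 0.0, 0.0, 0.0),
            seed=sub,
        )
        res = logistic_univariate(simulate_cohort(spec), 1)
        if res.estimable:
            fitted += 1
            if res.ci_low <= true_or <= res.ci_high:
                covered += 1
    return covered / fitted if fitted else float("nan")
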
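"""Detection-based sequencing-depth saturation curves.

Reads are allocated to community contigs multinomially in proportion to
abundance x length; per-contig breadth follows the Poisson-coverage form
``1 - exp(-per_bp_depth)`` and a contig is detected when breadth reaches the
threshold.  Subsamples across the depth grid are nested (each shallower
depth is a without-replacement subsample of the next deeper one), so the
detected set is monotone in depth for a fixed seed.

Yields are reported per million read *pairs*, labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mvi.io_model import QUALITY_TIERS, ValidationError

DEPTH_GRID_DEFAULT = (10_000, 100_000, 200_000, 1_000_000, 10_000_000, 20_000_000, 50_000_000, 100_000_000)
READ_LEN_DEFAULT = 150  # bp per mate; a pair contributes 2 * read_len bases


@dataclass
class DepthCurve:
    """Saturation curve: summary table plus per-depth detection masks."""

    table: pd.DataFrame
    detected: dict[int, np.ndarray]
    contig_ids: list[str]


def subsample_detect(
    abundance: np.ndarray,
    lengths: np.ndarray,
    depth_grid: tuple[int, ...] = DEPTH_GRID_DEFAULT,
    quality: np.ndarray | None = None,
    annotated: np.ndarray | None = None,
    breadth_min: float = 0.75,
    read_len: int = READ_LEN_DEFAULT,
    seed: int = 0,
) -> DepthCurve:
    """Trace VC detection across a grid of paired-end read depths."""
    grid = sorted(int(d) for d in depth_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("depth grid must be strictly increasing")
    if grid[0] < 0:
        raise ValidationError("negative depth")
    abundance = np.asarray(abundance, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if abundance.shape != lengths.shape:
        raise ValidationError("abundance and lengths must align")

    weights = abundance * lengths
    total = weights.sum()
    if total <= 0:
        raise ValidationError("community has no abundance mass")
    p = weights / total

    rng = np.random.default_rng(seed)
    counts_at: dict[int, np.ndarray] = {}
    deepest = grid[-1]
    counts_at[deepest] = rng.multinomial(deepest, p)
    for shallower, deeper in zip(reversed(grid[:-1]), reversed(grid)):
        counts_at[shallower] = rng.multivariate_hypergeometric(
            counts_at[deeper], shallower, method="marginals"
        )

    rows = []
    detected_at: dict[int, np.ndarray] = {}
    prev_n = 0
    prev_depth = 0
    for depth in grid:
        n_reads = counts_at[depth]
        per_bp = n_reads * (2.0 * read_len) / lengths
        breadth = 1.0 - np.exp(-per_bp)
        det = breadth >= breadth_min if depth > 0 else np.zeros_like(breadth, dtype=bool)
        detected_at[depth] = det
        n_det = int(det.sum())
        delta_m = (depth - prev_depth) / 1e6
        row = {
            "depth_read_pairs": depth,
            "n_vc_detected": n_det,
            "yield_per_million_read_pairs": (n_det - prev_n) / delta_m if delta_m > 0 else np.nan,
            "mean_len_kb": float(lengths[det].mean() / 1000.0) if n_det else np.nan,
            "max_len_kb": float(lengths[det].max() / 1000.0) if n_det else np.nan,
        }
        if quality is not None:
            for tier in QUALITY_TIERS:
                row[f"frac_{tier}"] = (
                    float((np.asarray(quality)[det] == tier).mean()) if n_det else np.nan
                )
        if annotated is not None:
            row["frac_annotated"] = (
                float(np.asarray(annotated, dtype=bool)[det].mean()) if n_det else np.nan
            )
        rows.append(row)
        prev_n, prev_depth = n_det, depth
    return DepthCurve(table=pd.DataFrame(rows), detected=detected_at, contig_ids=[])


def curve_summary(curve: DepthCurve, yield_eps: float = 1.0) -> dict[str, object]:
    """Locate the saturation knee: the first grid depth opening an interval
    whose marginal yield drops below *yield_eps* new VCs per million pairs.

    A curve whose yield never drops below the threshold has no knee and is
    flagged; a flat curve knees at the first grid point.
    """
    t = curve.table
    if len(t) < 3:
        raise ValidationError("depth grid too short for a saturation summary (<3 points)")
    depths = t["depth_read_pairs"].to_numpy()
    yields = t["yield_per_million_read_pairs"].to_numpy()

    knee = None
    for j in range(1, len(t)):
        if yields[j] < yield_eps:
            knee = int(depths[j - 1])
            break

    tier_cols = [c for c in t.columns if c.startswith("frac_") and c != "frac_annotated"]
    tier_stable = None
    if tier_cols and len(t) >= 2:
        last, prev = t.iloc[-1][tier_cols], t.iloc[-2][tier_cols]
        tier_stable = bool(np.nanmax(np.abs(last.to_numpy() - prev.to_numpy())) < 0.05)

    return {
        "knee_depth_read_pairs": knee,
        "no_knee": knee is None,
        "tier_fractions_stable": tier_stable,
        "final_n_vc": int(t["n_vc_detected"].iloc[-1]),
    }
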
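"""Nuclear immunofluorescence quantitation via the ellipsoid model.

Each nucleus is modelled as an ellipsoid with radii a and b measured on its
largest optical section and a z-extent (thickness): v = 4/3 * pi * a * b *
(thickness / 2).  Total fluorescence is mean intensity times volume.  Within
each experimental replicate the injected-group mean is normalized against
the control group (set to 1 arbitrary unit); groups are then compared with
the Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from reprosist.chromatin_profiles import rank_sum_test


def nucleus_volume(a: float, b: float, thickness: float) -> float:
    """Ellipsoid volume v = 4/3 * pi * a * b * (thickness / 2), in µm³."""
    if a <= 0 or b <= 0 or thickness <= 0:
        raise ValueError("radii and thickness must be positive")
    return (4.0 / 3.0) * np.pi * a * b * (thickness / 2.0)


def total_fluorescence(mean_fluorescence: float, volume: float) -> float:
    """Total fluorescence = mean fluorescence * ellipsoid volume."""
    if mean_fluorescence < 0 or volume < 0:
        raise ValueError("fluorescence and volume must be non-negative")
    return mean_fluorescence * volume


def normalize_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate group means, control normalized to 1.

    ``measurements`` needs columns ``radius_a``, ``radius_b``,
    ``thickness``, ``mean_fluorescence``, ``group`` (control/injected) and
    ``replicate``.  Returns one row per (replicate, group) with the raw and
    normalized mean total fluorescence.
    """
    required = {"radius_a", "radius_b", "thickness", "mean_fluorescence",
                "group", "replicate"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    df = measurements.copy()
    df["volume"] = [
        nucleus_volume(r.radius_a, r.radius_b, r.thickness)
        for r in df.itertuples()
    ]
    df["total"] = df["mean_fluorescence"] * df["volume"]

    rows = []
    for rep, sub in df.groupby("replicate"):
        groups = set(sub["group"])
        if groups != {"control", "injected"}:
            raise ValueError(f"replicate {rep!r} lacks a group "
                             f"(has {sorted(groups)})")
        means = sub.groupby("group")["total"].mean()
        if means["control"] == 0:
            raise ValueError(f"replicate {rep!r} has zero control mean")
        for group in ("control", "injected"):
            rows.append(dict(replicate=rep, group=group,
                             mean_total=means[group],
                             normalized=means[group] / means["control"]))
    return pd.DataFrame(rows)


def compare_groups(normalized: pd.DataFrame) -> tuple[float, float]:
    """Mann-Whitney comparison of per-replicate normalized means
    (injected vs control across replicates)."""
    a = normalized.loc[normalized["group"] == "injected", "normalized"]
    b = normalized.loc[normalized["group"] == "control", "normalized"]
    return rank_sum_test(a.to_numpy(), b.to_numpy())
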
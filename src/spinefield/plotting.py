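"""Optional matplotlib plots of the cord slice profiles.

Analogous to the standard tsDCS figures: slice-mean field magnitude and
longitudinal component along the cord, with spinal-segment boundaries
marked on the z axis.  Requires matplotlib (``pip install spinefield[plot]``).
"""

from __future__ import annotations

import pandas as pd

from .synthetic_anatomy import Landmarks

__all__ = ["plot_slice_profile"]


def plot_slice_profile(profiles: dict[str, pd.DataFrame],
                       landmarks: Landmarks,
                       quantity: str = "mean_e_norm",
                       tissue: str = "GM",
                       threshold: float | None = 0.15,
                       ax=None):
    """Plot slice-mean profiles of several runs against cord z.

    ``profiles`` maps montage names to slice-profile tables; segment
    boundaries appear as ticks on a secondary axis.  Returns the axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    for name, prof in profiles.items():
        sel = prof[(prof["tissue"] == tissue) & (prof["n_voxels"] > 0)]
        ax.plot(sel[quantity], sel["z_center"], label=name)
    if threshold is not None:
        ax.axvline(threshold, color="gray", ls="--", lw=0.8,
                   label=f"{threshold} V/m")
    segs = sorted(landmarks.segment_z_ranges.items(), key=lambda kv: kv[1][0])
    sec = ax.secondary_yaxis("right")
    sec.set_yticks([0.5 * (z0 + z1) for _, (z0, z1) in segs])
    sec.set_yticklabels([name for name, _ in segs], fontsize=6)
    for _, (z0, _) in segs:
        ax.axhline(z0, color="0.9", lw=0.5, zorder=0)
    ax.set_xlabel(f"{quantity} (V/m), {tissue}")
    ax.set_ylabel("z (mm, rostral up)")
    ax.legend(fontsize=7)
    return ax
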
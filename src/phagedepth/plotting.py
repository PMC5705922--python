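"""Display helpers (log scaling here is display-only and never feeds statistics)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def abundance_heatmap(rel_abundance: pd.DataFrame, samples: pd.DataFrame, path=None):
    """Contig x sample heatmap of log-scaled relative abundance, samples
    ordered by depth then date."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = samples.sort_values(["depth_m", "date"], kind="stable")["sample_id"]
    order = [s for s in order if s in rel_abundance.columns]
    mat = np.log10(rel_abundance[order] + 1e-6)
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xlabel("samples (depth-ordered)")
    ax.set_ylabel("contigs")
    fig.colorbar(im, ax=ax, label="log10 relative abundance")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def lysogeny_depth_profile(folds: pd.DataFrame, path=None):
    """Fold change of the prophage:capsid index versus depth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    ax.plot(folds["fold_vs_surface"], folds.index, "o-")
    ax.invert_yaxis()
    ax.set_xlabel("fold vs surface mean")
    ax.set_ylabel("depth (m)")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
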
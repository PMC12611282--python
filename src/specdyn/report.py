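"""Report figures: raw/corrected/periodic/aperiodic panels and stat maps.

All figures are rendered from a results bundle alone and are reproducible:
PNG metadata is fixed so rendering twice yields identical bytes.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["report"]

_SAVEKW = {"dpi": 110, "metadata": {"Software": "specdyn"}}


def _heatmap(ax, data, times, freqs, title, cmap="RdBu_r", symmetric=True):
    finite = data[np.isfinite(data)]
    if finite.size == 0:
        ax.set_axis_off()
        return
    if symmetric:
        v = np.nanpercentile(np.abs(finite), 98) or 1.0
        kw = {"vmin": -v, "vmax": v}
    else:
        kw = {}
    mesh = ax.pcolormesh(times, freqs, data, cmap=cmap, shading="nearest", **kw)
    ax.set_title(title, fontsize=9)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    plt.colorbar(mesh, ax=ax)


def report(bundle, outdir) -> list:
    """Render available figures; missing inputs skip figures with a note."""
    warnings.filterwarnings("ignore", message="Mean of empty slice",
                            category=RuntimeWarning)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    raw = bundle.tfr.get("raw") if bundle.tfr else None
    corrected = None
    if bundle.tfr:
        for name, tfr in bundle.tfr.items():
            if name != "raw":
                corrected = tfr
                break

    if raw is not None:
        fig, axes = plt.subplots(2, 2, figsize=(10, 7), constrained_layout=True)
        ga = 10 * np.log10(np.nanmean(raw.power, axis=(0, 1, 2)))
        _heatmap(axes[0, 0], ga, raw.times, raw.frequencies,
                 "raw power (dB, grand average)", cmap="viridis",
                 symmetric=False)
        if corrected is not None:
            gc = np.nanmean(corrected.power, axis=(0, 1, 2))
            _heatmap(axes[0, 1], gc, corrected.times, corrected.frequencies,
                     f"baseline-corrected ({corrected.params.get('baseline')})")
        else:
            axes[0, 1].set_axis_off()
        if bundle.params is not None:
            par = bundle.params
            gp = np.nanmean(par.periodic, axis=(0, 1, 2))
            _heatmap(axes[1, 0], gp, par.times, par.frequencies,
                     "periodic component (log10 power)", cmap="magma",
                     symmetric=False)
            expo = np.nanmean(par.exponent, axis=(0, 1, 2))
            ax = axes[1, 1]
            ax.plot(par.times, expo, color="k")
            ax.set_title("aperiodic exponent (grand average)", fontsize=9)
            ax.set_xlabel("time (s)")
            ax.set_ylabel("exponent")
        else:
            axes[1, 0].set_axis_off()
            axes[1, 1].set_axis_off()
        path = outdir / "decomposition.png"
        fig.savefig(path, **_SAVEKW)
        plt.close(fig)
        written.append(path)

    if bundle.params is not None:
        par = bundle.params
        fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
        for c in range(par.exponent.shape[1]):
            label = None
            if raw is not None and raw.condition_labels:
                label = "/".join(raw.condition_labels[c])
            ax.plot(par.times, np.nanmean(par.exponent[:, c], axis=(0, 1)),
                    label=label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("aperiodic exponent")
        ax.set_title("exponent timecourse by condition", fontsize=9)
        if raw is not None and raw.condition_labels:
            ax.legend(fontsize=6)
        path = outdir / "exponent_timecourse.png"
        fig.savefig(path, **_SAVEKW)
        plt.close(fig)
        written.append(path)

    if bundle.pacf is not None:
        rm = bundle.pacf
        fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
        _heatmap(ax, np.nanmean(rm.pacf, axis=(0, 1, 2)), rm.times,
                 rm.frequencies, "pACF (grand average)", cmap="magma",
                 symmetric=False)
        path = outdir / "pacf.png"
        fig.savefig(path, **_SAVEKW)
        plt.close(fig)
        written.append(path)

    for analysis, maps in (bundle.stats or {}).items():
        for term, sm in maps.items():
            if not np.any(np.isfinite(sm.r2_signed)):
                continue
            fig, ax = plt.subplots(figsize=(6, 3), constrained_layout=True)
            data = sm.r2_signed
            if data.ndim == 2:
                mesh = ax.pcolormesh(data, cmap="RdBu_r",
                                     vmin=-np.nanmax(np.abs(data)) or -1,
                                     vmax=np.nanmax(np.abs(data)) or 1,
                                     shading="nearest")
                ax.set_xlabel("timepoint")
                ax.set_ylabel("channel")
                plt.colorbar(mesh, ax=ax)
                sig = np.argwhere(sm.cluster_significant)
                if sig.size:
                    ax.scatter(sig[:, 1], sig[:, 0], s=4, c="yellow",
                               marker="o")
            else:
                ax.plot(np.nanmean(data, axis=0))
            ax.set_title(f"{analysis}: {term} (signed marginal R2)", fontsize=8)
            path = outdir / f"stats_{analysis}_{term.replace(':', 'x')}.png"
            fig.savefig(path, **_SAVEKW)
            plt.close(fig)
            written.append(path)
    return written
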
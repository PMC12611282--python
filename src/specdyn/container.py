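"""HDF5 container for epoched data and analysis results.

One self-describing file per run, with groups::

    /epochs            single-trial EEG + metadata
    /erp               trial-average waveforms
    /tfr/<name>        time-frequency power (raw or baseline-corrected)
    /params            spectral-parameterization maps
    /pacf              rhythmicity maps
    /stats/<analysis>/<term>   mass-univariate outputs
    /manifest          seed, config, versions, array hashes

Axes (times, frequencies) are always stored explicitly; unknown extra
groups written by newer minor schema versions are preserved on read.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from .erp import ERPData
from .rhythmicity import RhythmicityMap
from .specparam import ParameterizedTFR, SpecparamSettings
from .synth import EpochedData
from .tfr import TimeFrequencyRepresentation

__all__ = ["SCHEMA_VERSION", "ContainerError", "write_container",
           "read_container", "array_hash"]

SCHEMA_VERSION = "1.0"


class ContainerError(RuntimeError):
    """Unreadable, truncated or schema-incompatible container file."""


def array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _labels_to_json(labels):
    return json.dumps([list(l) for l in labels])


def _labels_from_json(s):
    return [tuple(l) for l in json.loads(s)]


def _write_epochs(g, data: EpochedData):
    g.create_dataset("samples", data=data.samples, compression="gzip",
                     compression_opts=1)
    g.create_dataset("times", data=data.times)
    g.create_dataset("reaction_times", data=data.reaction_times)
    g.create_dataset("accuracy", data=data.accuracy)
    g.attrs["sampling_rate"] = data.sampling_rate
    g.attrs["channel_names"] = json.dumps(list(data.channel_names))
    g.attrs["condition_labels"] = _labels_to_json(data.condition_labels)


def _read_epochs(g) -> EpochedData:
    return EpochedData(
        samples=g["samples"][()],
        sampling_rate=float(g.attrs["sampling_rate"]),
        times=g["times"][()],
        channel_names=json.loads(g.attrs["channel_names"]),
        condition_labels=_labels_from_json(g.attrs["condition_labels"]),
        reaction_times=g["reaction_times"][()],
        accuracy=g["accuracy"][()].astype(bool),
    )


def _write_tfr(g, tfr: TimeFrequencyRepresentation):
    g.create_dataset("power", data=tfr.power, compression="gzip",
                     compression_opts=1)
    g.create_dataset("frequencies", data=tfr.frequencies)
    g.create_dataset("times", data=tfr.times)
    if tfr.valid is not None:
        g.create_dataset("valid", data=tfr.valid)
    if tfr.missing_cells is not None:
        g.create_dataset("missing_cells", data=tfr.missing_cells)
    g.attrs["method"] = tfr.method
    g.attrs["params"] = json.dumps(tfr.params)
    g.attrs["output_rate"] = tfr.output_rate
    if tfr.condition_labels is not None:
        g.attrs["condition_labels"] = _labels_to_json(tfr.condition_labels)
    if tfr.channel_names is not None:
        g.attrs["channel_names"] = json.dumps(list(tfr.channel_names))


def _read_tfr(g) -> TimeFrequencyRepresentation:
    return TimeFrequencyRepresentation(
        power=g["power"][()],
        frequencies=g["frequencies"][()],
        times=g["times"][()],
        method=str(g.attrs["method"]),
        params=json.loads(g.attrs["params"]),
        output_rate=float(g.attrs["output_rate"]),
        valid=g["valid"][()].astype(bool) if "valid" in g else None,
        missing_cells=(g["missing_cells"][()].astype(bool)
                       if "missing_cells" in g else None),
        condition_labels=(_labels_from_json(g.attrs["condition_labels"])
                          if "condition_labels" in g.attrs else None),
        channel_names=(json.loads(g.attrs["channel_names"])
                       if "channel_names" in g.attrs else None),
    )


def _write_params(g, par: ParameterizedTFR):
    for name in ("offset", "exponent", "periodic", "r_squared",
                 "mean_abs_error", "n_peaks", "failed", "times",
                 "frequencies"):
        g.create_dataset(name, data=getattr(par, name))
    g.attrs["window"] = list(par.window)
    g.attrs["settings"] = json.dumps({
        "peak_width_limits": list(par.settings.peak_width_limits),
        "max_n_peaks": (None if np.isinf(par.settings.max_n_peaks)
                        else par.settings.max_n_peaks),
        "min_peak_height": par.settings.min_peak_height,
        "peak_threshold": par.settings.peak_threshold,
        "bw_std_edge": par.settings.bw_std_edge,
    })


def _read_params(g) -> ParameterizedTFR:
    s = json.loads(g.attrs["settings"])
    settings = SpecparamSettings(
        peak_width_limits=tuple(s["peak_width_limits"]),
        max_n_peaks=(np.inf if s["max_n_peaks"] is None else s["max_n_peaks"]),
        min_peak_height=s["min_peak_height"],
        peak_threshold=s["peak_threshold"],
        bw_std_edge=s["bw_std_edge"],
    )
    return ParameterizedTFR(
        offset=g["offset"][()], exponent=g["exponent"][()],
        periodic=g["periodic"][()], r_squared=g["r_squared"][()],
        mean_abs_error=g["mean_abs_error"][()], n_peaks=g["n_peaks"][()],
        failed=g["failed"][()].astype(bool), times=g["times"][()],
        frequencies=g["frequencies"][()],
        window=tuple(g.attrs["window"]), settings=settings,
    )


def _write_erp(g, erp: ERPData):
    g.create_dataset("waveform", data=erp.waveform, compression="gzip",
                     compression_opts=1)
    g.create_dataset("times", data=erp.times)
    g.create_dataset("n_trials", data=erp.n_trials)
    if erp.channel_names is not None:
        g.attrs["channel_names"] = json.dumps(list(erp.channel_names))
    if erp.condition_labels is not None:
        g.attrs["condition_labels"] = _labels_to_json(erp.condition_labels)


def _read_erp(g) -> ERPData:
    return ERPData(
        waveform=g["waveform"][()], times=g["times"][()],
        n_trials=g["n_trials"][()],
        channel_names=(json.loads(g.attrs["channel_names"])
                       if "channel_names" in g.attrs else None),
        condition_labels=(_labels_from_json(g.attrs["condition_labels"])
                          if "condition_labels" in g.attrs else None),
    )


def _write_pacf(g, rm: RhythmicityMap):
    g.create_dataset("pacf", data=rm.pacf, compression="gzip",
                     compression_opts=1)
    g.create_dataset("frequencies", data=rm.frequencies)
    g.create_dataset("times", data=rm.times)
    g.create_dataset("lags_cycles", data=rm.lags_cycles)
    g.attrs["window_cycles"] = rm.window_cycles
    g.attrs["n_cycles"] = rm.n_cycles


def _read_pacf(g) -> RhythmicityMap:
    return RhythmicityMap(
        pacf=g["pacf"][()], frequencies=g["frequencies"][()],
        times=g["times"][()], lags_cycles=g["lags_cycles"][()],
        window_cycles=float(g.attrs["window_cycles"]),
        n_cycles=float(g.attrs["n_cycles"]),
    )


def _write_statmaps(g, statmaps: dict):
    for term, sm in statmaps.items():
        tg = g.create_group(term.replace("/", "_"))
        for name in ("coef", "r2_signed", "p", "df", "fdr_significant",
                     "cluster_significant"):
            tg.create_dataset(name, data=getattr(sm, name))
        tg.attrs["term"] = sm.term
        tg.attrs["q"] = sm.q


def _read_statmaps(g) -> dict:
    from .mixedstats import StatMap

    out = {}
    for term in g:
        tg = g[term]
        out[str(tg.attrs["term"])] = StatMap(
            coef=tg["coef"][()], r2_signed=tg["r2_signed"][()],
            p=tg["p"][()], df=tg["df"][()],
            fdr_significant=tg["fdr_significant"][()].astype(bool),
            cluster_significant=tg["cluster_significant"][()].astype(bool),
            term=str(tg.attrs["term"]), q=float(tg.attrs["q"]),
        )
    return out


def write_container(obj, path, manifest: dict | None = None) -> str:
    """Write an object or a results bundle to an HDF5 container.

    ``obj`` may be an :class:`EpochedData` or a dict with any of the keys
    ``epochs``, ``erp``, ``tfr`` (dict name -> TFR), ``params``, ``pacf``,
    ``stats`` (dict analysis -> dict term -> StatMap).
    """
    if isinstance(obj, EpochedData):
        obj = {"epochs": obj}
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if obj.get("epochs") is not None:
            _write_epochs(f.create_group("epochs"), obj["epochs"])
        if obj.get("erp") is not None:
            _write_erp(f.create_group("erp"), obj["erp"])
        for name, tfr in (obj.get("tfr") or {}).items():
            _write_tfr(f.create_group(f"tfr/{name}"), tfr)
        if obj.get("params") is not None:
            _write_params(f.create_group("params"), obj["params"])
        if obj.get("pacf") is not None:
            _write_pacf(f.create_group("pacf"), obj["pacf"])
        for analysis, maps in (obj.get("stats") or {}).items():
            _write_statmaps(f.create_group(f"stats/{analysis}"), maps)
        mg = f.create_group("manifest")
        for key, value in (manifest or {}).items():
            mg.attrs[key] = (json.dumps(value)
                             if isinstance(value, (dict, list)) else value)
    return str(path)


def read_container(path):
    """Read a container back into a dict of objects.

    Raises :class:`ContainerError` on truncated files or unsupported major
    schema versions; extra groups from newer minor versions are ignored but
    do not fail the read.
    """
    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as exc:
        raise ContainerError(f"cannot open container {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ContainerError(f"{path} has no schema_version attribute")
        major = str(version).split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise ContainerError(
                f"unsupported schema version {version} (expected "
                f"{SCHEMA_VERSION}-compatible)"
            )
        out = {"schema_version": str(version)}
        if "epochs" in f:
            out["epochs"] = _read_epochs(f["epochs"])
        if "erp" in f:
            out["erp"] = _read_erp(f["erp"])
        if "tfr" in f:
            out["tfr"] = {name: _read_tfr(f["tfr"][name]) for name in f["tfr"]}
        if "params" in f:
            out["params"] = _read_params(f["params"])
        if "pacf" in f:
            out["pacf"] = _read_pacf(f["pacf"])
        if "stats" in f:
            out["stats"] = {name: _read_statmaps(f["stats"][name])
                            for name in f["stats"]}
        if "manifest" in f:
            out["manifest"] = {k: v for k, v in f["manifest"].attrs.items()}
    return out
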
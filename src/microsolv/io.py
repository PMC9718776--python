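"""Plain-text tabular I/O and run configuration.

All data interchange is TSV with explicit headers; metadata rides in
'#'-prefixed header lines.  Floats are written with 9 significant
digits so files are diff-able and round-trip stably.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .constants import M_CLUSTER_U, M_WATER_U
from .exceptions import ConfigError, ParameterError
from .signal import CHANNELS, IonYieldCurve
from .synthetic import GroundTruth
from .tker import KESpectrum

__all__ = [
    "read_ion_yields",
    "write_ion_yields",
    "read_ke_spectra",
    "write_ke_spectra",
    "read_mean_tker",
    "write_mean_tker",
    "read_truth",
    "write_truth",
    "write_report",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.9g"


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_ion_yields(path, curves: dict[str, IonYieldCurve], meta: dict | None = None) -> None:
    """Write delay scans of one or more channels to one TSV file."""
    frames = [curves[ch].to_frame() for ch in CHANNELS if ch in curves]
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ion_yields(path) -> dict[str, IonYieldCurve]:
    """Read a (delay_ps, yield, sigma, channel) TSV into per-channel curves."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParameterError(f"cannot parse ion-yield table {path}: {exc}") from exc
    required = {"delay_ps", "yield", "sigma", "channel"}
    if not required.issubset(df.columns):
        raise ParameterError(
            f"ion-yield table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    out = {}
    for ch, grp in df.groupby("channel"):
        grp = grp.sort_values("delay_ps")
        sigma = grp["sigma"].to_numpy()
        out[str(ch)] = IonYieldCurve(
            grp["delay_ps"].to_numpy(),
            grp["yield"].to_numpy(),
            None if np.all(np.isnan(sigma)) else sigma,
            channel=str(ch),
        )
    return out


def write_ke_spectra(path, spectra: list[KESpectrum], meta: dict | None = None) -> None:
    """Write delay-resolved spectra as one long-format TSV."""
    rows = []
    for s in spectra:
        rows.append(
            pd.DataFrame(
                {
                    "delay_ps": s.delay_ps if s.delay_ps is not None else np.nan,
                    "bin_lo_meV": s.bin_edges_mev[:-1],
                    "bin_hi_meV": s.bin_edges_mev[1:],
                    "counts": s.counts,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    header = {
        "m_fragment_u": spectra[0].m_fragment_u,
        "m_parent_u": spectra[0].m_parent_u,
        "is_tker": spectra[0].is_tker,
    }
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        fh.write(_meta_lines(header))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ke_spectra(path) -> list[KESpectrum]:
    meta = _read_meta(Path(path))
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParameterError(f"cannot parse spectra table {path}: {exc}") from exc
    required = {"delay_ps", "bin_lo_meV", "bin_hi_meV", "counts"}
    if not required.issubset(df.columns):
        raise ParameterError(
            f"spectra table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    m_frag = float(meta.get("m_fragment_u", M_WATER_U))
    m_par = float(meta.get("m_parent_u", M_CLUSTER_U))
    is_tker = meta.get("is_tker", "True") == "True"
    out = []
    for delay, grp in df.groupby("delay_ps", dropna=False, sort=True):
        grp = grp.sort_values("bin_lo_meV")
        edges = np.append(grp["bin_lo_meV"].to_numpy(), grp["bin_hi_meV"].to_numpy()[-1])
        out.append(
            KESpectrum(
                edges,
                grp["counts"].to_numpy(),
                delay_ps=None if pd.isna(delay) else float(delay),
                m_fragment_u=m_frag,
                m_parent_u=m_par,
                is_tker=is_tker,
            )
        )
    return out


def write_mean_tker(path, delays_ps, mean_mev, sigma_mev, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {"delay_ps": delays_ps, "mean_tker_meV": mean_mev, "sigma_meV": sigma_mev}
    )
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_mean_tker(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParameterError(f"cannot parse mean-TKER table {path}: {exc}") from exc
    required = {"delay_ps", "mean_tker_meV", "sigma_meV"}
    if not required.issubset(df.columns):
        raise ParameterError(
            f"mean-TKER table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    df = df.sort_values("delay_ps")
    return (
        df["delay_ps"].to_numpy(),
        df["mean_tker_meV"].to_numpy(),
        df["sigma_meV"].to_numpy(),
    )


def write_truth(path, truth: GroundTruth, seed: int | None = None) -> None:
    doc = {"ground_truth": truth.to_dict()}
    if seed is not None:
        doc["seed"] = int(seed)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path) -> tuple[GroundTruth, int | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    truth = GroundTruth.from_dict(doc["ground_truth"])
    seed = doc.get("seed")
    return truth, seed


def write_report(path, report: dict) -> None:
    """Serialize a flat key-value fit report as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)


# -- run configuration ----------------------------------------------------


class ModelDefaults(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tau_irf_fs: float = 381.0
    probe_fwhm_fs: float = 70.0
    rabi_omega0: float = 3.4
    mu_debye: float = 1.96
    e_pump_ev: float = 4.61
    m_fragment_u: float = M_WATER_U
    m_parent_u: float = M_CLUSTER_U


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_nfev: int | None = None
    mb_form: str = "3d"
    mb_min_delay_ps: float = 65.0
    baseline: str = "negative-delay"


class RunConfig(BaseModel):
    """Run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "."
    model: ModelDefaults = ModelDefaults()
    fit: FitOptions = FitOptions()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        try:
            data = yaml.safe_load(text) or {}
            return cls.model_validate(data)
        except (yaml.YAMLError, ValidationError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc


def load_config(path=None) -> RunConfig:
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(Path(path).read_text())
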
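"""Open file formats and cross-sample feature alignment.

The pipeline's currency is the *feature*: one detected LC-MS peak with m/z,
retention time, integrated area and apex intensity. Per-sample feature
tables travel as delimited text; MS/MS spectra as MGF; the aligned
samples x consensus-features matrix as delimited text with a sidecar
provenance file.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

MZ_MIN, MZ_MAX = 50.0, 1000.0  # acquisition m/z range

REQUIRED_COLUMNS = ("mz", "rt_min", "area", "intensity")


class FeatureTableError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    feature_id: str
    mz: float
    rt: float  # minutes
    area: float
    intensity: float
    sample_id: str
    ms2_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not (MZ_MIN <= self.mz <= MZ_MAX):
            raise FeatureTableError(
                f"feature {self.feature_id!r}: mz {self.mz} outside acquisition "
                f"range [{MZ_MIN}, {MZ_MAX}]"
            )
        if self.rt < 0 or self.area < 0 or self.intensity < 0:
            raise FeatureTableError(
                f"feature {self.feature_id!r}: rt/area/intensity must be >= 0"
            )


@dataclass
class FeatureTable:
    sample_id: str
    class_label: str
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise FeatureTableError(f"duplicate feature_ids in sample {self.sample_id!r}")
        for f in self.features:
            if f.sample_id != self.sample_id:
                raise FeatureTableError(
                    f"feature {f.feature_id!r} carries sample_id {f.sample_id!r}, "
                    f"table is {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class Ms2Spectrum:
    """One MS/MS scan: precursor m/z plus (fragment m/z, intensity) peaks."""

    spectrum_id: str
    precursor_mz: float
    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not (MZ_MIN <= self.precursor_mz <= MZ_MAX):
            raise FeatureTableError(
                f"spectrum {self.spectrum_id!r}: precursor {self.precursor_mz} "
                "outside acquisition range"
            )
        pk = tuple(sorted(self.peaks))
        if any(i <= 0 for _, i in pk):
            raise FeatureTableError(f"spectrum {self.spectrum_id!r}: non-positive peak intensity")
        object.__setattr__(self, "peaks", pk)

    @property
    def fragment_mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(
    path, sample_id: Optional[str] = None, class_label: str = "",
    sep: str = ",", rt_unit: str = "min",
) -> FeatureTable:
    """Read one per-sample feature table from delimited text.

    Header must name at least mz, rt_min, area, intensity (rt_sec accepted
    with ``rt_unit='sec'``). Rows violating the feature invariants are
    rejected with their line number.
    """
    df = pd.read_csv(path, sep=sep)
    rt_col = "rt_min" if rt_unit == "min" else "rt_sec"
    missing = [c for c in ("mz", rt_col, "area", "intensity") if c not in df.columns]
    if missing:
        raise FeatureTableError(f"{path}: missing required column(s) {missing}")
    if sample_id is None:
        sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else (
            os.path.splitext(os.path.basename(str(path)))[0]
        )
    features = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = row._asdict()
        try:
            rt = float(d[rt_col]) / (60.0 if rt_unit == "sec" else 1.0)
            features.append(Feature(
                feature_id=str(d.get("feature_id", f"F{i - 1:05d}")),
                mz=float(d["mz"]), rt=rt,
                area=float(d["area"]), intensity=float(d["intensity"]),
                sample_id=sample_id,
                ms2_ref=(str(d["ms2_ref"]) if d.get("ms2_ref") not in (None, "", float("nan"))
                         and d.get("ms2_ref") == d.get("ms2_ref") else None),
            ))
        except (TypeError, ValueError) as exc:
            raise FeatureTableError(f"{path}: line {i}: {exc}") from exc
    return FeatureTable(sample_id=sample_id, class_label=class_label, features=features)


def write_feature_table(table: FeatureTable, path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in table.features],
            "mz": [f"{f.mz:.5f}" for f in table.features],
            "rt_min": [f"{f.rt:.3f}" for f in table.features],
            "area": [f"{f.area:.2f}" for f in table.features],
            "intensity": [f"{f.intensity:.2f}" for f in table.features],
            "sample_id": table.sample_id,
            "ms2_ref": [f.ms2_ref or "" for f in table.features],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def apply_eic_filters(
    table: FeatureTable,
    min_area: float = 1000.0,
    min_intensity: float = 500.0,
    min_snr: float = 3.0,
    noise: Optional[Dict[str, float]] = None,
) -> FeatureTable:
    """Extracted-ion-chromatogram stage filters: area >= min_area,
    intensity >= min_intensity and, when per-feature noise estimates are
    supplied, intensity/noise >= min_snr. Thresholds are inclusive."""
    if min(min_area, min_intensity, min_snr) < 0:
        raise ValueError("thresholds must be >= 0")
    kept = []
    for f in table.features:
        if f.area < min_area or f.intensity < min_intensity:
            continue
        if noise is not None and f.feature_id in noise:
            n = noise[f.feature_id]
            if n > 0 and f.intensity / n < min_snr:
                continue
        kept.append(f)
    return FeatureTable(table.sample_id, table.class_label, kept)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path) -> List[Ms2Spectrum]:
    """Read MS/MS spectra from MGF (BEGIN IONS / PEPMASS / TITLE blocks)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            if "pepmass" not in params:
                raise FeatureTableError("MGF block without PEPMASS")
            title = str(params.get("title", f"spectrum{len(spectra)}"))
            peaks = tuple(zip(spec["m/z array"].tolist(), spec["intensity array"].tolist()))
            spectra.append(Ms2Spectrum(title, float(params["pepmass"][0]), peaks))
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path) -> None:
    entries = [
        {
            "m/z array": np.array([m for m, _ in s.peaks]),
            "intensity array": np.array([i for _, i in s.peaks]),
            "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz, "charge": "1-"},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def index_spectra(spectra: Sequence[Ms2Spectrum]) -> Dict[str, Ms2Spectrum]:
    return {s.spectrum_id: s for s in spectra}


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedMatrix:
    """samples x consensus-features area matrix.

    Zeros record non-detection (not NaN) so downstream scaling stays total.
    """

    consensus_mz: np.ndarray        # (n_features,)
    consensus_rt: np.ndarray        # (n_features,)
    values: np.ndarray              # (n_samples, n_features)
    sample_ids: List[str]
    labels: List[str]
    provenance: List[List[str]]     # per consensus feature: contributing feature ids

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m:.5f}@{t:.3f}" for m, t in zip(self.consensus_mz, self.consensus_rt)]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def write(self, matrix_path, provenance_path) -> None:
        df = self.to_frame()
        df.insert(0, "class_label", self.labels)
        df.to_csv(matrix_path)
        with open(provenance_path, "w") as fh:
            fh.write("consensus_mz,consensus_rt,feature_ids\n")
            for m, t, ids in zip(self.consensus_mz, self.consensus_rt, self.provenance):
                fh.write(f"{m:.5f},{t:.3f},{';'.join(ids)}\n")


def align_features(
    tables: Sequence[FeatureTable], ppm_tol: float = 5.0, rt_tol: float = 0.2,
) -> AlignedMatrix:
    """Greedy area-ranked centroid clustering across samples.

    Features sorted by descending area (ties: ascending m/z) seed clusters;
    each feature joins the nearest existing cluster whose area-weighted
    centroid is within both tolerances (nearest by ppm, then by RT), else
    seeds a new cluster. A sample's areas in a cluster are summed.
    """
    if not tables:
        raise ValueError("align_features needs at least one feature table")
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")

    feats = [(f, t.sample_id) for t in tables for f in t.features]
    feats.sort(key=lambda p: (-p[0].area, p[0].mz))

    # growing cluster state
    c_mz: List[float] = []
    c_rt: List[float] = []
    c_wt: List[float] = []
    members: List[List[Tuple[str, Feature]]] = []

    mz_arr = np.empty(0)
    rt_arr = np.empty(0)

    for f, sid in feats:
        if len(c_mz):
            dppm = np.abs(f.mz - mz_arr) / mz_arr * 1e6
            drt = np.abs(f.rt - rt_arr)
            ok = (dppm <= ppm_tol) & (drt <= rt_tol)
            if ok.any():
                idx = np.flatnonzero(ok)
                # nearest by ppm, tie-break by RT distance
                best = idx[np.lexsort((drt[idx], dppm[idx]))][0]
                w = c_wt[best]
                fw = max(f.area, 1e-12)
                c_mz[best] = (c_mz[best] * w + f.mz * fw) / (w + fw)
                c_rt[best] = (c_rt[best] * w + f.rt * fw) / (w + fw)
                c_wt[best] = w + fw
                members[best].append((sid, f))
                mz_arr[best] = c_mz[best]
                rt_arr[best] = c_rt[best]
                continue
        c_mz.append(f.mz)
        c_rt.append(f.rt)
        c_wt.append(max(f.area, 1e-12))
        members.append([(sid, f)])
        mz_arr = np.asarray(c_mz)
        rt_arr = np.asarray(c_rt)

    order = np.lexsort((c_rt, c_mz))
    sample_ids = [t.sample_id for t in tables]
    labels = [t.class_label for t in tables]
    pos = {s: i for i, s in enumerate(sample_ids)}
    values = np.zeros((len(tables), len(order)))
    provenance: List[List[str]] = []
    for j, k in enumerate(order):
        ids = []
        for sid, f in members[k]:
            values[pos[sid], j] += f.area
            ids.append(f.feature_id)
        provenance.append(ids)
    return AlignedMatrix(
        consensus_mz=mz_arr[order].copy(),
        consensus_rt=rt_arr[order].copy(),
        values=values,
        sample_ids=sample_ids,
        labels=labels,
        provenance=provenance,
    )
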
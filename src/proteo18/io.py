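"""File formats: mzML runs, PSM tables, configuration, CSV exports.

mzML reading and writing use a small lxml-based layer covering the subset of
the standard this tool consumes: centroided MS1 spectra with uncompressed or
zlib-compressed 32/64-bit float peak arrays.  The PSM
table is a documented tab-delimited dialect standing in for search-engine
output (columns: run_id, scan, sequence, charge, observed_mz, label_state,
proteins, score).  Quantification results export to RFC-4180 CSV at scan,
peptide, and protein levels, either as separate files or one concatenated
file with a ``level`` column.
"""

from __future__ import annotations

import base64
import re
import struct
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

from .chem import DEFAULT_FIXED_MODS
from .cluster import CHANNEL_NAMES, LabelState, Scan
from .protein import PeptideQuantRecord, ProteinQuantResult

__all__ = [
    "MzmlReadError",
    "ProfileSpectraError",
    "PsmTableError",
    "ConfigError",
    "PsmRecord",
    "Config",
    "load_config",
    "read_mzml",
    "write_mzml",
    "read_psm_table",
    "write_psm_table",
    "PSM_COLUMNS",
    "results_frames",
    "export_results",
]

PSM_COLUMNS = (
    "run_id",
    "scan",
    "sequence",
    "charge",
    "observed_mz",
    "label_state",
    "proteins",
    "score",
)


class MzmlReadError(RuntimeError):
    """Raised for unreadable or structurally unusable mzML input."""


class ProfileSpectraError(MzmlReadError):
    """Raised when MS1 spectra are profile-mode; centroided input is required."""


class PsmTableError(ValueError):
    """Raised for malformed PSM tables, naming the offending row."""


class ConfigError(ValueError):
    """Raised for missing or invalid configuration keys."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match consumed from the identification table."""

    run_id: str
    scan_number: int
    sequence: str
    charge: int
    observed_mz: float
    label_state: LabelState
    protein_accs: tuple[str, ...]
    score: float


@dataclass(frozen=True)
class Config:
    """Pipeline parameters.

    purity_p: fraction of 18O in the labeling water, in (0, 1].
    tol_ppm: m/z matching tolerance (matches a 10 ppm precursor tolerance).
    charge_evidence_min_fraction: minimum 13C-partner / monoisotope intensity
        ratio for charge evidence.
    """

    purity_p: float = 0.95
    tol_ppm: float = 10.0
    charge_evidence_min_fraction: float = 0.01
    min_unique_peptides: int = 2
    fixed_mods: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIXED_MODS.items()}
    )
    ratio_orientation: str = "heavy_over_light"
    match_mode: str = "intense"
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity_p <= 1.0:
            raise ConfigError("purity_p must lie in (0, 1]")
        if self.tol_ppm <= 0:
            raise ConfigError("tol_ppm must be positive")
        if self.charge_evidence_min_fraction <= 0:
            raise ConfigError("charge_evidence_min_fraction must be positive")
        if self.min_unique_peptides < 1:
            raise ConfigError("min_unique_peptides must be >= 1")
        if self.ratio_orientation not in ("heavy_over_light", "light_over_heavy"):
            raise ConfigError(f"unknown ratio_orientation {self.ratio_orientation!r}")


def load_config(path: str | Path) -> Config:
    """Load a TOML config file; ``purity_p`` is required explicitly."""
    raw = tomllib.loads(Path(path).read_text())
    if "purity_p" not in raw:
        raise ConfigError("purity_p required")
    known = {
        "purity_p",
        "tol_ppm",
        "charge_evidence_min_fraction",
        "min_unique_peptides",
        "fixed_mods",
        "ratio_orientation",
        "match_mode",
        "gap_tolerance",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "fixed_mods" in raw:
        raw["fixed_mods"] = {
            aa: {el: int(n) for el, n in delta.items()}
            for aa, delta in raw["fixed_mods"].items()
        }
    return Config(**raw)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_SCAN_RE = re.compile(r"scan=(\d+)")
_MZML_NS = "http://psi.hupo.org/ms/mzml"

# cvParam accessions consumed by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_params(element: etree._Element) -> dict[str, tuple[str, str]]:
    """accession -> (value, unitName) for the element's direct cvParams."""
    out = {}
    for cv in element.iterfind(f"{{{_MZML_NS}}}cvParam"):
        out[cv.get("accession")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def _decode_array(bda: etree._Element) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in params:
        import zlib

        raw = zlib.decompress(raw)
    elif _ACC_NO_COMPRESSION not in params:
        raise MzmlReadError("unsupported binary-array compression")
    if _ACC_F64 in params:
        return np.frombuffer(raw, dtype="<f8").astype(float)
    if _ACC_F32 in params:
        return np.frombuffer(raw, dtype="<f4").astype(float)
    raise MzmlReadError("binary array lacks a float-precision cvParam")


def read_mzml(path: str | Path) -> list[Scan]:
    """Read centroided spectra from an mzML file, sorted by scan number.

    MS levels are preserved (MS2 scans are kept but skipped by the cluster
    extension).  Profile-mode MS1 spectra and runs without any MS1 scan are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise MzmlReadError(f"mzML file not found: {path}")
    scans: list[Scan] = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MzmlReadError(f"malformed XML in {path}: {exc}") from exc
    for i, sp in enumerate(tree.iter(f"{{{_MZML_NS}}}spectrum")):
        params = _cv_params(sp)
        ms_level = int(params.get(_ACC_MS_LEVEL, ("1", ""))[0])
        if _ACC_PROFILE in params and ms_level == 1:
            raise ProfileSpectraError(
                f"{path}: MS1 spectrum {sp.get('id')} is profile-mode; "
                "centroided input is required"
            )
        m = _SCAN_RE.search(sp.get("id", ""))
        number = int(m.group(1)) if m else int(sp.get("index", i)) + 1
        rt = 0.0
        scan_el = sp.find(f"{{{_MZML_NS}}}scanList/{{{_MZML_NS}}}scan")
        if scan_el is not None:
            scan_params = _cv_params(scan_el)
            if _ACC_SCAN_START in scan_params:
                value, unit = scan_params[_ACC_SCAN_START]
                rt = float(value) * (60.0 if unit == "minute" else 1.0)
        mz = intensity = None
        for bda in sp.iterfind(
            f"{{{_MZML_NS}}}binaryDataArrayList/{{{_MZML_NS}}}binaryDataArray"
        ):
            arr_params = _cv_params(bda)
            if _ACC_MZ_ARRAY in arr_params:
                mz = _decode_array(bda)
            elif _ACC_INT_ARRAY in arr_params:
                intensity = _decode_array(bda)
        if mz is None or intensity is None:
            raise MzmlReadError(f"{path}: spectrum {sp.get('id')} lacks peak arrays")
        scans.append(
            Scan(
                scan_number=number,
                retention_time=rt,
                mz=mz,
                intensity=intensity,
                ms_level=ms_level,
            )
        )
    if not any(s.ms_level == 1 for s in scans):
        raise MzmlReadError(f"{path}: no MS1 scans")
    scans.sort(key=lambda s: s.scan_number)
    return scans


def _b64_doubles(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *map(float, values))
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{n}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="controllerType=0 controllerNumber=1 scan={scan}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(path: str | Path, scans: list[Scan], run_id: str = "run1") -> None:
    """Write centroided scans as minimal mzML (64-bit float, no compression)."""
    parts = [_MZML_HEADER.format(run_id=escape(run_id), n=len(scans))]
    for i, s in enumerate(scans):
        mz_b64 = _b64_doubles(s.mz)
        int_b64 = _b64_doubles(s.intensity)
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                scan=s.scan_number,
                npeaks=len(s.mz),
                ms_level=s.ms_level,
                rt=repr(float(s.retention_time)),
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read the tab-delimited PSM table; errors name the offending data row.

    Duplicated (run, scan) rows are both kept: one MS2 scan may legitimately
    be searched as both the modified and the unmodified form.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise PsmTableError(f"failed to read PSM table {path}: {exc}") from exc
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PsmTableError(f"{path}: missing column(s) {missing}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            charge = int(row.charge)
            if charge < 1:
                raise ValueError(f"charge must be >= 1, got {charge}")
            scan = int(row.scan)
            if scan < 1:
                raise ValueError(f"scan must be >= 1, got {scan}")
            state = LabelState(row.label_state.strip().lower())
            accs = tuple(a for a in row.proteins.split(";") if a)
            if not accs:
                raise ValueError("no protein accession")
            records.append(
                PsmRecord(
                    run_id=row.run_id,
                    scan_number=scan,
                    sequence=row.sequence,
                    charge=charge,
                    observed_mz=float(row.observed_mz),
                    label_state=state,
                    protein_accs=accs,
                    score=float(row.score) if row.score else float("nan"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise PsmTableError(f"{path} row {i}: {exc}") from exc
    return records


def write_psm_table(path: str | Path, records: list[PsmRecord]) -> None:
    rows = [
        {
            "run_id": r.run_id,
            "scan": r.scan_number,
            "sequence": r.sequence,
            "charge": r.charge,
            "observed_mz": repr(r.observed_mz),
            "label_state": r.label_state.value,
            "proteins": ";".join(r.protein_accs),
            "score": r.score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------


def results_frames(
    peptide_records: list[PeptideQuantRecord],
    proteins: list[ProteinQuantResult],
) -> dict[str, pd.DataFrame]:
    """Build the scan-, peptide-, and protein-level result tables."""
    scan_rows = []
    pep_rows = []
    for r in peptide_records:
        base = {
            "protein": r.protein_acc,
            "sequence": str(r.peptide),
            "charge": r.charge,
            "label_state": r.label_state.value,
        }
        for o in r.observations:
            row = dict(base)
            row["scan"] = o.scan_number
            row["retention_time"] = o.retention_time
            for name, value in zip(CHANNEL_NAMES, o.a):
                row[f"int_{name}"] = value
            row["charge_evidence_16O"] = o.charge_evidence_16O
            row["charge_evidence_18O2"] = o.charge_evidence_18O2
            scan_rows.append(row)
        pep_rows.append(
            {
                **base,
                "light": r.light,
                "heavy": r.heavy,
                "ratio": r.ratio,
                "log2_ratio": r.log2_ratio,
                "inverse_ratio": (1.0 / r.ratio) if r.ratio else None,
                "n_scans": r.n_scans,
                "scan_first": r.scan_range[0],
                "scan_last": r.scan_range[1],
                "flags": ";".join(sorted(r.flags)),
                "excluded": r.excluded,
                "audit": r.audit,
            }
        )
    prot_rows = [
        {
            "protein": p.protein_acc,
            "ratio": p.ratio,
            "log2_ratio": p.log2_ratio,
            "robust_scale": p.robust_scale,
            "n_peptides_used": p.n_peptides_used,
            "n_unique_peptides": p.n_unique_peptides,
            "peptide_weights": ";".join(repr(w) for w in p.peptide_weights),
            "status": p.status,
        }
        for p in proteins
    ]
    return {
        "scan": pd.DataFrame(scan_rows),
        "peptide": pd.DataFrame(pep_rows),
        "protein": pd.DataFrame(prot_rows),
    }


def export_results(
    frames: dict[str, pd.DataFrame],
    outdir: str | Path,
    levels: tuple[str, ...] = ("scan", "peptide", "protein"),
    mode: str = "separate",
) -> list[Path]:
    """Write result tables as CSV; ``single`` concatenates with a level column.

    Output is deterministic for identical inputs (no timestamps; full-repr
    float formatting with dot decimal separator).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [lv for lv in levels if lv not in frames]
    if unknown:
        raise ValueError(f"unknown result level(s): {unknown}")
    written: list[Path] = []
    if mode == "separate":
        for lv in levels:
            path = outdir / f"{lv}s.csv"
            frames[lv].to_csv(path, index=False)
            written.append(path)
    elif mode == "single":
        tagged = []
        for lv in levels:
            df = frames[lv].copy()
            df.insert(0, "level", lv)
            tagged.append(df)
        path = outdir / "quant_all.csv"
        pd.concat(tagged, ignore_index=True).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown export mode {mode!r}")
    return written
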
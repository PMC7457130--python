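"""Readers, writers and core containers for SNP-array CNV analysis.

All on-disk artifacts are plain tab-separated text.  Internal genomic
coordinates are 1-based inclusive base pairs throughout the package; UCSC
inputs (0-based half-open, e.g. cytoBand.txt) are converted on read.

Containers
----------
ProbeMap            ordered genomic markers shared by every sample
SampleIntensities   per-sample BAF/LRR tracks aligned to a ProbeMap
ClinicalRecord      one patient's phenotypes and recurrence outcome
CytobandMap         optional cytoband intervals for region labelling

Missing intensity values are encoded as NaN and excluded from every mean
and denominator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ProbeMap",
    "SampleIntensities",
    "ClinicalRecord",
    "CytobandMap",
    "read_intensities",
    "read_intensities_matrix",
    "write_intensities",
    "write_segments",
    "read_segments",
    "read_clinical",
    "write_clinical",
    "load_cytobands",
    "read_mcr_table",
    "write_mcr_table",
    "to_zero_based_half_open",
    "from_zero_based_half_open",
    "chrom_sort_key",
    "AUTOSOMES",
]


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates the format contract."""


AUTOSOMES = tuple(str(c) for c in range(1, 23))

SIZE_LARGE_CM = 4.3  # tumors strictly above this diameter form the "large" group

GENDERS = ("female", "male")
HISTORIES = ("primary", "recurrent")
WHO_GRADES = ("I", "II", "III")
LOCATIONS = ("skull-base", "non-skull-base")
SIMPSON_GRADES = ("I", "II", "III", "IV")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; chromosome names are bare ('1', 'X')."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def chrom_sort_key(chrom: str):
    """Genomic ordering: 1..22 numerically, then X, Y, then anything else."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    if c == "X":
        return (1, 0, "")
    if c == "Y":
        return (1, 1, "")
    return (2, 0, c)


def to_zero_based_half_open(start_bp: int, end_bp: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open (UCSC/BED)."""
    return start_bp - 1, end_bp


def from_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval (UCSC/BED) -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# ProbeMap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic markers (probe id, chromosome, 1-based position).

    Probes are sorted by (chromosome, position) with positions strictly
    increasing within each chromosome and unique probe ids.
    """

    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.probe_ids, dtype=object)
        chrom = np.asarray([normalize_chrom(c) for c in self.chromosomes], dtype=object)
        pos = np.asarray(self.positions, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValidationError("probe map columns have unequal lengths")
        if np.any(pos <= 0):
            raise ValidationError("probe positions must be positive integers")
        order = sorted(range(len(pid)), key=lambda i: (chrom_sort_key(chrom[i]), pos[i]))
        pid, chrom, pos = pid[order], chrom[order], pos[order]
        for i in range(1, len(pos)):
            if chrom[i] == chrom[i - 1] and pos[i] == pos[i - 1]:
                raise ValidationError(
                    f"duplicate probe position chr{chrom[i]}:{pos[i]} "
                    f"({pid[i - 1]!r}, {pid[i]!r})"
                )
        if len(set(pid)) != len(pid):
            raise ValidationError("probe ids are not unique")
        object.__setattr__(self, "probe_ids", pid)
        object.__setattr__(self, "chromosomes", chrom)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def chrom_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice covering each chromosome, in genome order."""
        out: dict[str, slice] = {}
        start = 0
        chroms = self.chromosomes
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def n_probes_chrom(self, chrom: str) -> int:
        return int(np.sum(self.chromosomes == normalize_chrom(chrom)))

    def subset(self, mask: np.ndarray) -> "ProbeMap":
        return ProbeMap(self.probe_ids[mask], self.chromosomes[mask], self.positions[mask])


@dataclass
class SampleIntensities:
    """BAF and LRR tracks for one sample, aligned to a ProbeMap.

    NaN marks a missing value; non-missing BAF must lie in [0, 1].
    """

    sample_id: str
    baf: np.ndarray
    lrr: np.ndarray

    def __post_init__(self):
        self.baf = np.asarray(self.baf, dtype=float)
        self.lrr = np.asarray(self.lrr, dtype=float)
        if self.baf.shape != self.lrr.shape or self.baf.ndim != 1:
            raise ValidationError("BAF and LRR must be 1-D arrays of equal length")
        ok = np.isnan(self.baf) | ((self.baf >= 0.0) & (self.baf <= 1.0))
        if not np.all(ok):
            i = int(np.argmin(ok))
            raise ValidationError(
                f"sample {self.sample_id!r}: BAF {self.baf[i]} at probe index {i} "
                "outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.baf)


# ---------------------------------------------------------------------------
# Intensity i/o
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["sample_id", "probe_id", "chromosome", "position", "baf", "lrr"]
_LONG_ALIASES = {
    "sampleid": "sample_id", "sample": "sample_id", "sample_id": "sample_id",
    "probeid": "probe_id", "probe": "probe_id", "probe_id": "probe_id", "snp name": "probe_id",
    "chr": "chromosome", "chrom": "chromosome", "chromosome": "chromosome",
    "position": "position", "pos": "position",
    "baf": "baf", "b allele freq": "baf",
    "lrr": "lrr", "log r ratio": "lrr",
}


def _canon_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    renamed = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _LONG_ALIASES:
            renamed[col] = _LONG_ALIASES[key]
    df = df.rename(columns=renamed)
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_intensities(
    path,
    probe_map: ProbeMap | None = None,
    include_xy: bool = False,
) -> tuple[ProbeMap, list[SampleIntensities]]:
    """Read a long-format intensity TSV (sample, probe, chr, pos, BAF, LRR).

    All samples are aligned to a single ProbeMap built from (or checked
    against) the probe coordinates in the file.  Probes on X/Y are dropped
    unless ``include_xy``; missing BAF/LRR values are kept as NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": str, "chromosome": str})
    df = _canon_columns(df, path)
    df["chromosome"] = df["chromosome"].map(normalize_chrom)
    if not include_xy:
        df = df[df["chromosome"].isin(AUTOSOMES)]
    if df.empty:
        raise ValidationError(f"{path}: no probes after chromosome filtering")

    bad = df["baf"].notna() & ((df["baf"] < 0) | (df["baf"] > 1))
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"{path}: BAF {row['baf']} outside [0, 1] "
            f"(sample {row['sample_id']}, probe {row['probe_id']})"
        )

    probes = df.drop_duplicates("probe_id")[["probe_id", "chromosome", "position"]]
    pm = ProbeMap(
        probes["probe_id"].to_numpy(object),
        probes["chromosome"].to_numpy(object),
        probes["position"].to_numpy(),
    )
    if probe_map is not None:
        if list(probe_map.probe_ids) != list(pm.probe_ids):
            raise ValidationError(f"{path}: probes disagree with the supplied probe map")
        pm = probe_map

    index = {p: i for i, p in enumerate(pm.probe_ids)}
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        baf = np.full(len(pm), np.nan)
        lrr = np.full(len(pm), np.nan)
        idx = grp["probe_id"].map(index)
        if idx.isna().any():
            raise ValidationError(f"{path}: sample {sid} has probes absent from the probe map")
        baf[idx.to_numpy(int)] = grp["baf"].to_numpy(float)
        lrr[idx.to_numpy(int)] = grp["lrr"].to_numpy(float)
        samples.append(SampleIntensities(str(sid), baf, lrr))
    return pm, samples


def read_intensities_matrix(
    baf_path, lrr_path, probe_map_path, include_xy: bool = False
) -> tuple[ProbeMap, list[SampleIntensities]]:
    """Read matrix-form intensities: probes x samples BAF and LRR TSVs plus a
    probe-map TSV (probe_id, chromosome, position)."""
    pm_df = pd.read_csv(probe_map_path, sep="\t", comment="#", dtype={"chromosome": str})
    pm_df = pm_df.rename(columns={c: str(c).strip().lower() for c in pm_df.columns})
    for col in ("probe_id", "chromosome", "position"):
        if col not in pm_df.columns:
            raise ValidationError(f"{probe_map_path}: missing column {col!r}")
    pm_df["chromosome"] = pm_df["chromosome"].map(normalize_chrom)
    if not include_xy:
        pm_df = pm_df[pm_df["chromosome"].isin(AUTOSOMES)]
    pm = ProbeMap(
        pm_df["probe_id"].to_numpy(object),
        pm_df["chromosome"].to_numpy(object),
        pm_df["position"].to_numpy(),
    )
    baf = pd.read_csv(baf_path, sep="\t", comment="#", index_col=0)
    lrr = pd.read_csv(lrr_path, sep="\t", comment="#", index_col=0)
    if list(baf.columns) != list(lrr.columns):
        raise ValidationError("BAF and LRR matrices have different sample columns")
    baf = baf.reindex(pm.probe_ids)
    lrr = lrr.reindex(pm.probe_ids)
    samples = [
        SampleIntensities(str(sid), baf[sid].to_numpy(float), lrr[sid].to_numpy(float))
        for sid in baf.columns
    ]
    return pm, samples


def write_intensities(path, probe_map: ProbeMap, samples: Sequence[SampleIntensities]) -> None:
    """Write samples in the long tab-separated format read_intensities expects."""
    for s in samples:
        if len(s) != len(probe_map):
            raise ValidationError(f"sample {s.sample_id} not aligned to probe map")
    n, k = len(probe_map), len(samples)
    df = pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in samples], n),
            "probe_id": np.tile(probe_map.probe_ids, k),
            "chromosome": np.tile(probe_map.chromosomes, k),
            "position": np.tile(probe_map.positions, k),
            "baf": np.concatenate([s.baf for s in samples]) if k else [],
            "lrr": np.concatenate([s.lrr for s in samples]) if k else [],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


def write_probe_map(path, probe_map: ProbeMap) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchromosome\tposition\n")
        for i in range(len(probe_map)):
            fh.write(
                f"{probe_map.probe_ids[i]}\t{probe_map.chromosomes[i]}\t"
                f"{probe_map.positions[i]}\n"
            )


# ---------------------------------------------------------------------------
# Segment i/o  (BED-like TSV, 1-based inclusive)
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_probes", "mean_lrr", "state"]


def write_segments(calls: Iterable, path, header_comment: str | None = None) -> None:
    """Write segments/calls as a BED-like TSV (1-based inclusive coordinates).

    Accepts RawSegment (state written as '.') or SegmentCall objects; the
    optional ``loh_fraction`` is appended as an extra column when present.
    """
    calls = list(calls)
    has_loh = any(getattr(c, "loh_fraction", None) is not None for c in calls)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        cols = SEGMENT_COLUMNS + (["loh_fraction"] if has_loh else [])
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            state = getattr(c, "state", None) or "."
            row = [
                str(getattr(c, "sample_id", ".")),
                str(c.chromosome),
                str(c.start_bp),
                str(c.end_bp),
                str(c.n_probes),
                f"{c.mean_lrr:.6g}",
                state,
            ]
            if has_loh:
                lf = getattr(c, "loh_fraction", None)
                row.append("" if lf is None else f"{lf:.6g}")
            fh.write("\t".join(row) + "\n")


def read_segments(path) -> pd.DataFrame:
    """Read a segment TSV back into a validated DataFrame.

    Rejects end < start and overlapping segments within one sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing segment columns {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["end_bp"] < df["start_bp"]).any():
        bad = df[df["end_bp"] < df["start_bp"]].iloc[0]
        raise ValidationError(
            f"{path}: segment end < start at chr{bad['chrom']}:"
            f"{bad['start_bp']}-{bad['end_bp']}"
        )
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start_bp")
        prev_end = -1
        for _, row in grp.iterrows():
            if row["start_bp"] <= prev_end:
                raise ValidationError(
                    f"{path}: overlapping segments for sample {sample} on chr{chrom}"
                )
            prev_end = row["end_bp"]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


@dataclass
class ClinicalRecord:
    """One patient's phenotypes plus the recurrence-free-survival outcome.

    ``size_group`` is derived: 'large' iff diameter strictly above 4.3 cm
    (the cohort median), else 'small'.
    """

    patient_id: str
    gender: str
    age: float
    history: str
    who_grade: str
    subtype: str
    location: str
    bone_invasion: bool
    edema: bool
    multiple: bool
    diameter_cm: float
    simpson: str
    radiotherapy: bool
    followup_months: float
    recurrence_event: bool
    size_group: str = field(init=False)

    def __post_init__(self):
        def check(value, allowed, name):
            if value not in allowed:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name} {value!r} not in {allowed}"
                )

        check(self.gender, GENDERS, "gender")
        check(self.history, HISTORIES, "history")
        check(self.who_grade, WHO_GRADES, "who_grade")
        check(self.location, LOCATIONS, "location")
        check(self.simpson, SIMPSON_GRADES, "simpson")
        if not self.diameter_cm > 0:
            raise ValidationError(f"patient {self.patient_id!r}: diameter must be > 0")
        if self.followup_months < 0:
            raise ValidationError(f"patient {self.patient_id!r}: negative follow-up")
        self.size_group = "large" if self.diameter_cm > SIZE_LARGE_CM else "small"


_CLINICAL_FIELDS = [f.name for f in fields(ClinicalRecord) if f.init]
_BOOL_FIELDS = {"bone_invasion", "edema", "multiple", "radiotherapy", "recurrence_event"}
_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_flag(value, field_name, patient) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"patient {patient!r}: {field_name} {value!r} is not yes/no")


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    missing = [c for c in _CLINICAL_FIELDS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing clinical columns {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        pid = row["patient_id"]
        for name in _CLINICAL_FIELDS:
            v = row[name]
            if name in _BOOL_FIELDS:
                kwargs[name] = _parse_flag(v, name, pid)
            elif name in ("age", "diameter_cm", "followup_months"):
                kwargs[name] = float(v)
            else:
                kwargs[name] = str(v).strip()
        records.append(ClinicalRecord(**kwargs))
    if len({r.patient_id for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate patient ids")
    return records


def write_clinical(path, records: Sequence[ClinicalRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CLINICAL_FIELDS) + "\n")
        for r in records:
            row = []
            for name in _CLINICAL_FIELDS:
                v = getattr(r, name)
                if name in _BOOL_FIELDS:
                    row.append("yes" if v else "no")
                else:
                    row.append(str(v))
            fh.write("\t".join(row) + "\n")


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by patient id (size_group included)."""
    rows = [{f: getattr(r, f) for f in _CLINICAL_FIELDS + ["size_group"]} for r in records]
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# Cytobands
# ---------------------------------------------------------------------------


@dataclass
class CytobandMap:
    """Cytoband intervals (1-based inclusive) for labelling genomic positions.

    ``label`` returns e.g. '22q11.1'; positions outside every band fall back
    to a plain 'chrN:pos' coordinate label.
    """

    bands: dict[str, list[tuple[int, int, str]]]

    def label(self, chrom: str, pos: int) -> str:
        chrom = normalize_chrom(chrom)
        for start, end, name in self.bands.get(chrom, ()):
            if start <= pos <= end:
                return f"{chrom}{name}"
        return f"chr{chrom}:{pos}"


def load_cytobands(path) -> CytobandMap:
    """Load a UCSC cytoBand.txt file (0-based half-open) into 1-based bands."""
    bands: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            chrom = normalize_chrom(parts[0])
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad coordinates") from exc
            if end0 <= start0:
                raise ValidationError(f"{path}:{lineno}: empty or inverted band")
            start, end = from_zero_based_half_open(start0, end0)
            bands.setdefault(chrom, []).append((start, end, parts[3]))
    for chrom, ivs in bands.items():
        ivs.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{path}: overlapping bands {chrom}{n1} and {chrom}{n2}"
                )
    return CytobandMap(bands)


# ---------------------------------------------------------------------------
# MCR tables (Table-2-like layout)
# ---------------------------------------------------------------------------

MCR_COLUMNS = [
    "cytoband", "type", "chrom", "start_bp", "end_bp",
    "size_kb", "g_score", "q_value", "frequency_percent", "carriers",
]


def write_mcr_table(regions: Iterable, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(MCR_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                f"{r.cytoband}\t{r.type}\t{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t"
                f"{r.size_kb:.6g}\t{r.g_score:.6g}\t{r.q_value:.6g}\t"
                f"{r.frequency_percent:.6g}\t{','.join(r.carrier_ids)}\n"
            )


def read_mcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "carriers": str})
    missing = [c for c in MCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing MCR columns {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["carriers"] = df["carriers"].fillna("")
    return df
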
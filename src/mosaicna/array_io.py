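"""I/O for probe tables, manifests, call tables, gene BEDs and distances.

File conventions
----------------
* Probe tables are tab-delimited "Final Report"-like files with a header
  naming (in any order, with flexible capitalisation) a probe id, chromosome,
  position, Log R Ratio, B Allele Freq and genotype column.
* All internal genomic coordinates are 1-based inclusive; BED export
  converts to 0-based half-open.
* Chromosome names are normalised by stripping a leading ``chr`` prefix and
  ordered naturally (1..22, X, Y).
* Numbers are written with ``%.6g`` so round trips are lossless at six
  significant digits and never locale-dependent.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mosaicna")

__all__ = [
    "FormatError",
    "ProbeSeries",
    "Manifest",
    "read_probe_table",
    "write_probe_table",
    "read_manifest",
    "write_manifest",
    "read_calls",
    "write_calls",
    "write_calls_bed",
    "read_gene_bed",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a level prefix."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# chromosome naming

_CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(_CHROM_ORDER)}

GENOTYPES = ("AA", "AB", "BB", "NC")


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix and canonicalise case (``chrx`` -> ``X``)."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.upper() in ("X", "Y", "MT") else s


def chrom_sort_key(name: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, then anything else lexically."""
    return (_CHROM_RANK.get(name, len(_CHROM_ORDER)), name)


def _order_chroms(chroms) -> list[str]:
    return sorted(set(chroms), key=chrom_sort_key)


# ---------------------------------------------------------------------------
# ProbeSeries

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "lrr", "baf", "gtype"]


@dataclass
class ProbeSeries:
    """One sample's ordered SNP-array probes.

    ``probes`` holds columns ``probe_id, chrom, pos, lrr, baf, gtype``,
    sorted by (chromosome, position) with unique positions per chromosome.
    BAF may be NaN only where the genotype is ``NC`` (no call).
    """

    sample_id: str
    probes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.probes = _validate_probes(self.probes, self.sample_id)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def chroms(self) -> list[str]:
        return _order_chroms(self.probes["chrom"])

    def autosomal_mask(self) -> np.ndarray:
        c = self.probes["chrom"].to_numpy()
        return np.isin(c, [str(i) for i in range(1, 23)])

    def chrom_slices(self) -> list[tuple[str, int, int]]:
        """(chrom, start_index, end_index) half-open row ranges, in order."""
        chroms = self.probes["chrom"].to_numpy()
        out = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], start, i))
                start = i
        return out

    def same_grid(self, other: "ProbeSeries") -> None:
        """Raise FormatError naming the first discordant probe if grids differ."""
        a, b = self.probes, other.probes
        if len(a) != len(b):
            raise FormatError(
                f"probe grids differ in length: {self.sample_id}={len(a)}, "
                f"{other.sample_id}={len(b)}"
            )
        same = (a["chrom"].to_numpy() == b["chrom"].to_numpy()) & (
            a["pos"].to_numpy() == b["pos"].to_numpy()
        )
        if not same.all():
            i = int(np.flatnonzero(~same)[0])
            raise FormatError(
                f"probe grids differ at row {i}: "
                f"{a['chrom'].iat[i]}:{a['pos'].iat[i]} vs "
                f"{b['chrom'].iat[i]}:{b['pos'].iat[i]}"
            )


def _validate_probes(df: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing column(s): {', '.join(missing)}")
    df = df.loc[:, PROBE_COLUMNS].copy()
    chrom = df["chrom"].astype(str)
    cmap = {u: normalize_chrom(u) for u in chrom.unique()}
    df["chrom"] = chrom.map(cmap)

    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        rows = list(df.index[pos.isna()][:5])
        raise FormatError(f"non-numeric or missing position at row(s) {rows}")
    df["pos"] = pos.astype(np.int64)
    if (df["pos"] <= 0).any():
        raise FormatError("positions must be positive 1-based coordinates")

    df["lrr"] = pd.to_numeric(df["lrr"], errors="coerce").astype(float)
    df["baf"] = pd.to_numeric(df["baf"], errors="coerce").astype(float)
    df["gtype"] = df["gtype"].astype(str).str.upper()
    bad_gt = ~df["gtype"].isin(GENOTYPES)
    if bad_gt.any():
        raise FormatError(
            f"unknown genotype call(s): {sorted(set(df['gtype'][bad_gt]))[:5]}"
        )

    baf = df["baf"].to_numpy()
    out_of_range = (baf < 0) | (baf > 1)
    if out_of_range.any():
        rows = list(df.index[out_of_range][:5])
        raise FormatError(f"BAF outside [0, 1] at row(s) {rows}")
    nan_baf = np.isnan(baf)
    not_nc = df["gtype"].to_numpy() != "NC"
    if (nan_baf & not_nc).any():
        rows = list(df.index[nan_baf & not_nc][:5])
        raise FormatError(f"missing BAF with called genotype at row(s) {rows}")

    rmap = {c: chrom_sort_key(c)[0] for c in df["chrom"].unique()}
    rank = df["chrom"].map(rmap)
    order = np.lexsort((df["pos"].to_numpy(), rank.to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        logger.info("probe table for %s was unsorted; sorting", sample_id)
        df = df.iloc[order]
    df = df.reset_index(drop=True)

    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        i = int(df.index[dup][0])
        raise FormatError(
            f"duplicate position {df['chrom'].iat[i]}:{df['pos'].iat[i]}"
        )
    return df


# header aliases for Final-Report-like probe tables (canonicalised by
# lower-casing and dropping spaces/underscores/dots)
_PROBE_ALIASES = {
    "probe_id": {"snpname", "snp", "probe", "probeid", "name", "snpid"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"position", "pos", "mapinfo"},
    "lrr": {"logrratio", "lrr"},
    "baf": {"ballelefreq", "ballelefrequency", "baf"},
    "gtype": {"gtype", "genotype", "gt", "gencall"},
}


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def read_probe_table(path, sample_id: str | None = None) -> ProbeSeries:
    """Read a Final-Report-like TSV into a validated :class:`ProbeSeries`.

    Columns are matched by name (order-free); a missing required column
    raises :class:`FormatError` naming it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": str, "chrom": str})
    mapping: dict[str, str] = {}
    for col in df.columns:
        key = _canon(col)
        for canonical, aliases in _PROBE_ALIASES.items():
            if key in aliases and canonical not in mapping:
                mapping[canonical] = col
    missing = [c for c in PROBE_COLUMNS if c not in mapping]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    out = df[[mapping[c] for c in PROBE_COLUMNS]].copy()
    out.columns = PROBE_COLUMNS
    if sample_id is None:
        sample_id = _stem(path)
    return ProbeSeries(sample_id=sample_id, probes=out)


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


def write_probe_table(series: ProbeSeries, path) -> None:
    """Write a ProbeSeries using canonical Final-Report-like headers."""
    df = series.probes.rename(
        columns={
            "probe_id": "SNP Name",
            "chrom": "Chr",
            "pos": "Position",
            "lrr": "Log R Ratio",
            "baf": "B Allele Freq",
            "gtype": "GType",
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Manifest

ROLES = ("CONTROL", "UM", "PT")
MANIFEST_COLUMNS = ["subject", "sample", "role", "tissue", "distance_cm", "subtype"]


@dataclass
class Manifest:
    """Cohort sample sheet: one row per sample, linked to a subject.

    Every subject with a UM row must also have at least one CONTROL row.
    ``distance_cm`` (edge-to-edge UM-to-tumor distance) and ``subtype``
    (molecular subtype label) are optional annotations.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("subject", "sample", "role"):
            if col not in df.columns:
                raise FormatError(f"manifest missing column: {col}")
        for col in MANIFEST_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["role"] = df["role"].astype(str).str.upper()
        bad = ~df["role"].isin(ROLES)
        if bad.any():
            raise FormatError(
                f"manifest roles must be in {ROLES}; got "
                f"{sorted(set(df['role'][bad]))}"
            )
        if df["sample"].duplicated().any():
            dup = df["sample"][df["sample"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sample id in manifest: {dup}")
        df["distance_cm"] = pd.to_numeric(df["distance_cm"], errors="coerce")
        for subj, grp in df.groupby("subject"):
            if (grp["role"] == "UM").any() and not (grp["role"] == "CONTROL").any():
                raise FormatError(f"subject {subj} has UM sample(s) but no CONTROL")
        self.table = df.loc[:, MANIFEST_COLUMNS].reset_index(drop=True)

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject"]))

    def samples_for(self, subject: str, role: str | None = None) -> list[str]:
        t = self.table[self.table["subject"] == subject]
        if role is not None:
            t = t[t["role"] == role.upper()]
        return list(t["sample"])


def read_manifest(path) -> Manifest:
    return Manifest(
        pd.read_csv(path, sep="\t", comment="#", dtype={"subject": str, "sample": str})
    )


def write_manifest(manifest: Manifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# call tables

CALL_COLUMNS = [
    "subject",
    "sample",
    "chrom",
    "start",
    "end",
    "class",
    "n_probes",
    "size_bp",
    "mean_lrr",
    "baf_split",
    "est_fraction",
    "flags",
]
# extra diagnostic columns written when present
CALL_EXTRA_COLUMNS = ["lrr_fraction", "imbalance_z", "n_informative"]


def empty_calls() -> pd.DataFrame:
    df = pd.DataFrame(columns=CALL_COLUMNS + CALL_EXTRA_COLUMNS)
    return df.astype(
        {
            "start": np.int64,
            "end": np.int64,
            "n_probes": np.int64,
            "size_bp": np.int64,
            "mean_lrr": float,
            "baf_split": float,
            "est_fraction": float,
            "lrr_fraction": float,
            "imbalance_z": float,
            "n_informative": np.int64,
        },
        errors="ignore",
    )


def _validate_calls(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    for col in ("start", "end", "n_probes", "size_bp"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    for col in ("mean_lrr", "baf_split", "est_fraction"):
        df[col] = pd.to_numeric(df[col]).astype(float)
    df["flags"] = df["flags"].fillna("").astype(str).replace("nan", "")
    if (df["end"] < df["start"]).any():
        raise FormatError("call with end < start")
    if not (df["size_bp"] == df["end"] - df["start"] + 1).all():
        raise FormatError("size_bp must equal end - start + 1")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write an aberration call table as TSV (1-based inclusive coords)."""
    if len(calls) == 0:
        cols = CALL_COLUMNS + [c for c in CALL_EXTRA_COLUMNS if c in calls.columns]
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return
    df = _validate_calls(calls)
    cols = CALL_COLUMNS + [c for c in CALL_EXTRA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"subject": str, "sample": str, "chrom": str, "flags": str},
    )
    if len(df) == 0:
        return empty_calls()
    return _validate_calls(df)


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """Export calls as BED (0-based half-open; class in the name field)."""
    with open(path, "w") as fh:
        if len(calls) == 0:
            return
        df = _validate_calls(calls)
        for _, row in df.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t"
                f"{row['class']}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# gene BED

def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED of gene intervals into 1-based inclusive coordinates.

    Returns a DataFrame with columns ``gene, chrom, start, end``.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED needs >=4 fields (name required)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise FormatError(f"{path}:{ln}: empty or inverted interval")
            rows.append((name, normalize_chrom(chrom), start + 1, end))
    if not rows:
        raise FormatError(f"{path}: no gene intervals")
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
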
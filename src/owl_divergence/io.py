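"""Input/output for trait, genotype and climate tables plus result reports.

Trait and climate tables are delimited text with a header row; genotypes are
read and written in Genepop format (the community standard for microsatellite
archives) or as a long delimited table.  Results are emitted as one
machine-readable JSON file plus human-readable TSV tables, byte-stable for a
fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected tabular/genotype format."""


SIDES = ("dorsal", "ventral")

#: Canonical trait-table columns.  Input headers are matched case-insensitively
#: and may be renamed via a user-supplied column map.
TRAIT_COLUMNS = (
    "individual_id",
    "population_id",
    "year",
    "side",
    "morph",
    "measurer_id",
    "total_length",
    "plumulaceous_length",
    "barbs_per_cm",
    "barbules_per_mm",
    "measurement_id",
)

NUMERIC_TRAIT_COLUMNS = (
    "total_length",
    "plumulaceous_length",
    "barbs_per_cm",
    "barbules_per_mm",
)

RESPONSE_TRAITS = ("plumulaceous_length", "barbs_per_cm", "barbules_per_mm")

MISSING = -1  # sentinel allele code for a missing genotype call


@dataclass
class TraitTable:
    """Long-format repeated feather measurements with grouping labels.

    One row per measured feather side; `rejected` records input rows dropped
    during validation as ``(input_row_index, reason)`` so that
    ``n_input_rows == len(data) + len(rejected)`` always holds.
    """

    data: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)
    n_input_rows: int = 0

    def __post_init__(self) -> None:
        if self.n_input_rows == 0:
            self.n_input_rows = len(self.data) + len(self.rejected)
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trait table missing columns: {missing}")
        bad_side = set(df["side"].unique()) - set(SIDES)
        if bad_side:
            raise FormatError(f"unknown feather side labels: {sorted(bad_side)}")
        if not df["morph"].isin([0, 1]).all():
            raise FormatError("morph must be binary (brown=1, grey=0)")
        # each individual belongs to exactly one population and one morph
        for col in ("population_id", "morph"):
            per_ind = df.groupby("individual_id")[col].nunique()
            multi = per_ind[per_ind > 1]
            if len(multi):
                raise FormatError(
                    f"individuals mapped to multiple {col} values: "
                    f"{list(multi.index[:5])}"
                )
        if self.n_input_rows != len(df) + len(self.rejected):
            raise FormatError("row accounting violated: input != stored + rejected")

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population_id"].unique())


@dataclass
class GenotypeTable:
    """Diploid genotypes: individuals x loci, unordered integer allele pairs.

    ``calls`` has shape (n_individuals, n_loci, 2); a missing call stores
    ``MISSING`` in both slots (missingness is locus-wise).
    """

    individual_ids: list[str]
    population_ids: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.population_ids = np.asarray(self.population_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise FormatError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise FormatError("missingness must be locus-wise (both alleles)")
        valid = (self.calls > 0) | (self.calls == MISSING)
        if not valid.all():
            raise FormatError("allele codes must be positive integers or MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population_ids.tolist()))

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.loci.index(l) for l in loci]
        return GenotypeTable(
            individual_ids=list(self.individual_ids),
            population_ids=self.population_ids.copy(),
            loci=list(loci),
            calls=self.calls[:, idx, :].copy(),
        )


@dataclass
class ClimateTable:
    """Per-population mean winter temperature (degC) and precipitation (mm)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("population_id", "mean_winter_temp", "mean_winter_precip")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"climate table missing columns: {missing}")
        dup = self.data["population_id"].duplicated()
        if dup.any():
            dupes = self.data.loc[dup, "population_id"].tolist()
            raise FormatError(f"duplicate population rows: {dupes}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def value(self, population_id: str, column: str) -> float:
        row = self.data[self.data["population_id"] == population_id]
        if row.empty:
            raise KeyError(population_id)
        return float(row.iloc[0][column])


@dataclass
class AnalysisConfig:
    """Run configuration for the full divergence analysis."""

    traits: Sequence[str] = RESPONSE_TRAITS
    sides: Sequence[str] = SIDES
    #: random-effect terms per trait (population always; year per the default)
    random_terms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "plumulaceous_length": ("population_id", "year"),
            "barbs_per_cm": ("population_id", "year"),
            "barbules_per_mm": ("population_id", "year"),
        }
    )
    #: fixed-effect terms per trait (mini-formula tokens, see reml.build_design)
    fixed_terms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "plumulaceous_length": ("1", "morph", "z(total_length)"),
            "barbs_per_cm": ("1", "morph", "C(measurer_id)"),
            "barbules_per_mm": ("1", "morph", "C(measurer_id)"),
        }
    )
    n_permutations: int = 10_000
    max_missing: float = 0.20
    seed: int = 0
    output_dir: str = "results"
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if not (0.0 < self.max_missing <= 1.0):
            raise ValueError("missing-locus threshold must lie in (0, 1]")


# ---------------------------------------------------------------------------
# trait table


def _normalise_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    return df


_MORPH_NAMES = {"brown": 1, "grey": 0, "gray": 0, "1": 1, "0": 0}


def read_trait_table(
    path: str | Path,
    dialect: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TraitTable:
    """Read a long-format trait table from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header naming the canonical columns
        (case-insensitive; remappable via ``column_map``).
    dialect
        Field delimiter; ``None`` sniffs comma/tab/semicolon.
    column_map
        Mapping from input header name to canonical column name.

    Rows whose plumulaceous length exceeds the total length, or in which every
    trait column is missing, are rejected and reported (never silently
    dropped).  An unparseable numeric cell raises :class:`FormatError` naming
    the row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect, engine="python", dtype=str)
    df = _normalise_columns(df, column_map)
    missing_cols = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path.name}: missing mandatory column(s) {missing_cols}"
        )
    n_input = len(df)

    out = pd.DataFrame(index=df.index)
    for col in ("individual_id", "population_id", "measurer_id", "measurement_id"):
        out[col] = df[col].astype(str).str.strip()
    out["side"] = df["side"].astype(str).str.strip().str.lower()

    for col in ("year",) + NUMERIC_TRAIT_COLUMNS:
        raw = df[col].astype(str).str.strip()
        empty = raw.isin(["", "nan", "NA", "na", "None"]) | df[col].isna()
        parsed = pd.to_numeric(raw.where(~empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            i = int(bad.idxmax())
            raise FormatError(
                f"{path.name}: unparseable numeric cell at row {i}, "
                f"column {col!r}: {raw[i]!r}"
            )
        out[col] = parsed
    if out["year"].isna().any():
        i = int(out["year"].isna().idxmax())
        raise FormatError(f"{path.name}: missing year at row {i}")
    out["year"] = out["year"].astype(int)

    morph_raw = df["morph"].astype(str).str.strip().str.lower()
    morph = morph_raw.map(_MORPH_NAMES)
    if morph.isna().any():
        i = int(morph.isna().idxmax())
        raise FormatError(
            f"{path.name}: unrecognised morph code at row {i}: {morph_raw[i]!r}"
        )
    out["morph"] = morph.astype(int)

    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(out), dtype=bool)
    both = out["plumulaceous_length"].notna() & out["total_length"].notna()
    viol = both & (out["plumulaceous_length"] > out["total_length"])
    for i in out.index[viol]:
        rejected.append((int(i), "plumulaceous_length > total_length"))
        keep[out.index.get_loc(i)] = False
    all_missing = out[list(NUMERIC_TRAIT_COLUMNS)].isna().all(axis=1)
    for i in out.index[all_missing & ~viol]:
        rejected.append((int(i), "all trait columns missing"))
        keep[out.index.get_loc(i)] = False
    if rejected:
        warnings.warn(
            f"{path.name}: rejected {len(rejected)} row(s): "
            f"{rejected[:5]}", stacklevel=2
        )
    out = out.loc[keep, list(TRAIT_COLUMNS)].reset_index(drop=True)
    return TraitTable(data=out, rejected=rejected, n_input_rows=n_input)


def write_trait_table(table: TraitTable, path: str | Path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str = "genepop") -> GenotypeTable:
    """Read diploid genotypes from Genepop text or a long delimited table."""
    if format == "genepop":
        return _read_genepop(path)
    if format == "long_table":
        return _read_long_genotypes(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genepop(path: str | Path) -> GenotypeTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path.name}: truncated genepop file")
    # line 0 is a free-text title; loci follow, one per line or comma-separated
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        line = lines[i].strip()
        if "," in line:
            # an individual record straying into the locus section
            tail = line.split(",", 1)[1].split()
            if tail and all(t.isdigit() and len(t) in (4, 6) for t in tail):
                raise FormatError(
                    f"{path.name}: line {i + 1}: individual record outside "
                    "any Pop block"
                )
        chunk = [t.strip() for t in line.split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise FormatError(f"{path.name}: no locus names before first Pop line")

    individual_ids: list[str] = []
    population_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_index += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if pop_index == 0:
            raise FormatError(
                f"{path.name}: line {i + 1}: individual outside any Pop block"
            )
        if "," not in line:
            raise FormatError(
                f"{path.name}: line {i + 1}: expected 'name , genotypes'"
            )
        name, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"{path.name}: line {i + 1}: {len(fields)} genotype fields "
                f"for {len(loci)} loci"
            )
        calls = []
        for locus, fld in zip(loci, fields):
            if len(fld) % 2 != 0 or len(fld) not in (4, 6):
                raise FormatError(
                    f"{path.name}: line {i + 1}: allele string {fld!r} at "
                    f"locus {locus} has invalid length"
                )
            w = len(fld) // 2
            a1, a2 = int(fld[:w]), int(fld[w:])
            if a1 == 0 or a2 == 0:
                calls.append((MISSING, MISSING))
            else:
                calls.append((a1, a2))
        individual_ids.append(name.strip())
        population_ids.append(f"pop{pop_index}")
        rows.append(calls)
        i += 1
    if not rows:
        raise FormatError(f"{path.name}: no individuals found")
    return GenotypeTable(
        individual_ids=individual_ids,
        population_ids=np.array(population_ids, dtype=object),
        loci=loci,
        calls=np.array(rows, dtype=np.int64),
    )


def _read_long_genotypes(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep=None, engine="python")
    df = _normalise_columns(df, None)
    required = ("individual_id", "population_id", "locus", "allele1", "allele2")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"long genotype table missing columns: {missing}")
    loci = sorted(df["locus"].unique())
    inds = list(dict.fromkeys(df["individual_id"].astype(str)))
    pop_of = dict(
        zip(df["individual_id"].astype(str), df["population_id"].astype(str))
    )
    calls = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int64)
    ind_idx = {v: k for k, v in enumerate(inds)}
    loc_idx = {v: k for k, v in enumerate(loci)}
    for _, row in df.iterrows():
        a1 = int(row["allele1"]) if not pd.isna(row["allele1"]) else 0
        a2 = int(row["allele2"]) if not pd.isna(row["allele2"]) else 0
        if a1 > 0 and a2 > 0:
            calls[ind_idx[str(row["individual_id"])], loc_idx[row["locus"]]] = (
                a1,
                a2,
            )
    return GenotypeTable(
        individual_ids=inds,
        population_ids=np.array([pop_of[i] for i in inds], dtype=object),
        loci=loci,
        calls=calls,
    )


def write_genepop(
    g: GenotypeTable, path: str | Path, title: str = "owl-divergence export"
) -> None:
    """Write genotypes as Genepop text with 3-digit allele codes.

    Population labels are not representable in Genepop (blocks are anonymous),
    so individuals are grouped into Pop blocks in sorted population order and
    read back with labels pop1..popK.
    """
    if (g.calls > 999).any():
        raise FormatError("allele codes exceed 3 digits; cannot write genepop")
    lines = [title]
    lines.extend(g.loci)
    order = sorted(set(g.population_ids.tolist()))
    for pop in order:
        lines.append("Pop")
        for i in np.flatnonzero(g.population_ids == pop):
            fields = []
            for l in range(len(g.loci)):
                a1, a2 = g.calls[i, l]
                if a1 == MISSING:
                    fields.append("000000")
                else:
                    fields.append(f"{a1:03d}{a2:03d}")
            lines.append(f"{g.individual_ids[i]} , " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# climate


def read_climate_table(path: str | Path, dialect: str | None = None) -> ClimateTable:
    """Read the per-population winter climate table (one row per population)."""
    df = pd.read_csv(path, sep=dialect, engine="python")
    df = _normalise_columns(df, None)
    required = ("population_id", "mean_winter_temp", "mean_winter_precip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"climate table missing columns: {missing}")
    df["population_id"] = df["population_id"].astype(str)
    for col in ("mean_winter_temp", "mean_winter_precip"):
        df[col] = pd.to_numeric(df[col])
    return ClimateTable(data=df[list(required)])


def write_climate_table(table: ClimateTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def _jsonify(obj: Any) -> Any:
    """Convert nested dataclasses/arrays/NaN to JSON-safe plain types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(report: Any, path: str | Path) -> list[Path]:
    """Write a ComparisonReport as report.json plus per-block TSV tables.

    Output is deterministic (sorted keys, fixed float repr) so identical
    runs produce byte-identical files.  Returns the written paths.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    payload = _jsonify(report.to_dict() if hasattr(report, "to_dict") else report)
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(jpath)

    for block, rows in _tsv_blocks(payload):
        tpath = outdir / f"{block}.tsv"
        pd.DataFrame(rows).to_csv(tpath, sep="\t", index=False)
        written.append(tpath)
    return written


def _tsv_blocks(payload: Mapping[str, Any]) -> Iterable[tuple[str, list[dict]]]:
    pst = payload.get("pst_estimates") or []
    rows = [
        {
            "trait": e.get("trait"),
            "side": e.get("side"),
            "pst": e.get("pst"),
            "pst_se": e.get("pst_se"),
        }
        for e in pst
    ]
    yield "pst_estimates", rows

    fst = payload.get("fst") or {}
    per_locus = fst.get("per_locus") or {}
    yield "fst_loci", [
        {"locus": k, "fst": per_locus[k]} for k in sorted(per_locus)
    ]

    corr = payload.get("climate_correlations") or {}
    yield "climate_correlations", [
        {
            "analysis": k,
            "r": corr[k].get("r"),
            "p": corr[k].get("p"),
            "n": corr[k].get("n"),
        }
        for k in sorted(corr)
    ]
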
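"""Reading, validation, and recoding of genotype, founder, intensity and map data.

All genotype calls are held internally as small integer codes:

* sample genotypes: ``0 = AA``, ``1 = AB``, ``2 = BB``, ``-1 = missing``;
* founder alleles:  ``0 = A``,  ``1 = B``, ``-1 = missing``,

where allele A is, by convention, the allele that was most frequent among
the eight founder strains (ties broken alphabetically by nucleotide).

On disk everything is plain CSV: genotype/founder/intensity tables have a
header row of sample (or founder) identifiers and the marker identifier in
the first column; the genetic map has columns ``marker,chr,pos`` with
positions in cM.  A YAML control file names the individual CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# genotype codes
GENO_NA = -1
GENO_AA = 0
GENO_AB = 1
GENO_BB = 2
GENO_LABELS = {GENO_AA: "AA", GENO_AB: "AB", GENO_BB: "BB", GENO_NA: "NA"}

# founder allele codes
ALLELE_NA = -1
ALLELE_A = 0
ALLELE_B = 1
ALLELE_LABELS = {ALLELE_A: "A", ALLELE_B: "B", ALLELE_NA: "NA"}

N_FOUNDERS = 8
FOUNDER_LABELS = tuple("ABCDEFGH")

#: Tokens accepted as missing data in any input table.
MISSING_TOKENS = {"", "-", "--", "N", "NA", "NaN", "nan", "NAN"}

_GENO_TOKEN_TO_CODE = {"AA": GENO_AA, "AB": GENO_AB, "BA": GENO_AB, "BB": GENO_BB}
_FOUNDER_TOKEN_TO_CODE = {"A": ALLELE_A, "B": ALLELE_B}
# heterozygous founder tokens: should not occur in inbred strains; treated as
# missing and counted separately so the caller can report them.
_FOUNDER_HET_TOKENS = {"H", "AB", "BA"}

NUCLEOTIDES = ("A", "C", "G", "T")


def _chrom_sort_key(name: str):
    """Numeric chromosomes first in numeric order, then others alphabetically."""
    s = str(name)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker genetic map: chromosome assignment and position in cM.

    ``table`` is indexed by marker id with columns ``chromosome`` (str) and
    ``position_cM`` (float).  Markers are kept sorted by chromosome, then
    position, with ties broken by marker id.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()[:10]
            raise ValueError(f"duplicate marker ids in map: {dups}")
        if (t["position_cM"] < 0).any():
            raise ValueError("map positions must be non-negative")
        t = t.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_cM"] = t["position_cM"].astype(float)
        t = t.rename_axis("marker").reset_index()
        t["_ckey"] = [_chrom_sort_key(c) for c in t["chromosome"]]
        # chromosome order, then position, ties broken by marker id
        t = t.sort_values(["_ckey", "position_cM", "marker"], kind="stable")
        self.table = t.drop(columns="_ckey").set_index("marker")

    @property
    def marker_ids(self) -> pd.Index:
        return self.table.index

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.table["chromosome"])
        return list(seen)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c.isdigit()]

    def markers_on(self, chromosome: str) -> pd.Index:
        return self.table.index[self.table["chromosome"] == str(chromosome)]

    def positions_on(self, chromosome: str) -> np.ndarray:
        sel = self.table["chromosome"] == str(chromosome)
        return self.table.loc[sel, "position_cM"].to_numpy()


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype calls (integer coded) plus sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``nominal_sex``
    (``"M"``/``"F"``/missing) and ``generation`` (nullable integer).
    """

    calls: pd.DataFrame
    sample_meta: pd.DataFrame = None

    def __post_init__(self):
        c = self.calls
        if c.index.duplicated().any():
            raise ValueError("duplicate marker ids in genotype matrix")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids in genotype matrix")
        valid = {GENO_NA, GENO_AA, GENO_AB, GENO_BB}
        vals = set(np.unique(c.to_numpy()))
        if not vals <= valid:
            raise ValueError(f"invalid genotype codes: {sorted(vals - valid)}")
        self.calls = c.astype(np.int8).rename_axis(index="marker", columns="sample")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"nominal_sex": pd.NA, "generation": pd.NA}, index=c.columns
            )
        meta = self.sample_meta.reindex(c.columns)
        if "nominal_sex" not in meta.columns:
            meta["nominal_sex"] = pd.NA
        if "generation" not in meta.columns:
            meta["generation"] = pd.NA
        meta["generation"] = pd.array(meta["generation"], dtype="Int64")
        self.sample_meta = meta

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def validate_against(self, gmap: GeneticMap) -> None:
        missing = self.marker_ids.difference(gmap.marker_ids)
        if len(missing):
            raise ValueError(
                f"{len(missing)} genotyped markers absent from map, e.g. "
                f"{missing.tolist()[:10]}"
            )

    def to_strings(self) -> pd.DataFrame:
        return self.calls.replace(GENO_LABELS).astype(str)

    @classmethod
    def from_strings(cls, table: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        codes, n_bad = _parse_geno_tokens(table)
        if n_bad:
            logger.warning("%d unparseable genotype calls set to missing", n_bad)
        return cls(codes, sample_meta)


@dataclass
class FounderGenotypes:
    """Markers x 8 founder strains, homozygous calls coded 0 = A, 1 = B, -1 = NA."""

    calls: pd.DataFrame

    def __post_init__(self):
        c = self.calls
        if c.shape[1] != N_FOUNDERS:
            raise ValueError(f"expected {N_FOUNDERS} founder columns, got {c.shape[1]}")
        if c.index.duplicated().any():
            raise ValueError("duplicate marker ids in founder genotypes")
        valid = {ALLELE_NA, ALLELE_A, ALLELE_B}
        vals = set(np.unique(c.to_numpy()))
        if not vals <= valid:
            raise ValueError(f"invalid founder allele codes: {sorted(vals - valid)}")
        self.calls = c.astype(np.int8).rename_axis(index="marker", columns="founder")

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def founder_ids(self) -> pd.Index:
        return self.calls.columns

    def to_strings(self) -> pd.DataFrame:
        return self.calls.replace(ALLELE_LABELS).astype(str)


@dataclass
class IntensityMatrix:
    """Two-channel allele probe intensities (markers x samples, array units).

    ``x`` is the allele-A channel and ``y`` the allele-B channel; both are
    non-negative with identical shape and labels.
    """

    x: pd.DataFrame
    y: pd.DataFrame

    def __post_init__(self):
        if not self.x.index.equals(self.y.index) or not self.x.columns.equals(self.y.columns):
            raise ValueError("intensity channels must share markers and samples")
        for name, df in (("x", self.x), ("y", self.y)):
            arr = df.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError(f"negative values in {name} channel")
        self.x = self.x.astype(float)
        self.y = self.y.astype(float)

    @property
    def marker_ids(self) -> pd.Index:
        return self.x.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.x.columns

    def average(self) -> pd.DataFrame:
        """Per-marker average of the two channels."""
        return (self.x + self.y) / 2.0


@dataclass
class DatasetBundle:
    """Everything one QC run needs, as loaded from a control file."""

    genotypes: GenotypeMatrix
    founders: FounderGenotypes
    gmap: GeneticMap
    intensities: IntensityMatrix | None = None


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _parse_geno_tokens(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    out = np.full(table.shape, GENO_NA, dtype=np.int8)
    n_bad = 0
    values = table.to_numpy(dtype=object)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            tok = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            if tok in _GENO_TOKEN_TO_CODE:
                out[i, j] = _GENO_TOKEN_TO_CODE[tok]
            elif tok not in MISSING_TOKENS:
                n_bad += 1
    return pd.DataFrame(out, index=table.index, columns=table.columns), n_bad


def _parse_founder_tokens(table: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    out = np.full(table.shape, ALLELE_NA, dtype=np.int8)
    n_bad = 0
    n_het = 0
    values = table.to_numpy(dtype=object)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            tok = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            if tok in _FOUNDER_TOKEN_TO_CODE:
                out[i, j] = _FOUNDER_TOKEN_TO_CODE[tok]
            elif tok in _FOUNDER_HET_TOKENS:
                n_het += 1
            elif tok not in MISSING_TOKENS:
                n_bad += 1
    return pd.DataFrame(out, index=table.index, columns=table.columns), n_bad, n_het


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_map(path) -> GeneticMap:
    """Read a genetic map CSV with columns ``marker,chr,pos`` (pos in cM)."""
    df = pd.read_csv(path, dtype={"marker": str, "chr": str})
    if not {"marker", "chr", "pos"}.issubset(df.columns):
        raise ValueError("map file needs columns marker,chr,pos")
    table = df.set_index("marker").rename(
        columns={"chr": "chromosome", "pos": "position_cM"}
    )[["chromosome", "position_cM"]]
    return GeneticMap(table)


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample covariates CSV: columns ``id,sex,generation``."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    meta = df.set_index("id").rename(columns={"sex": "nominal_sex"})
    if "generation" in meta.columns:
        meta["generation"] = pd.array(meta["generation"], dtype="Int64")
    return meta


def read_genotypes(
    path,
    gmap: GeneticMap | None = None,
    markers_in: str = "rows",
    sample_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a genotype call CSV into a :class:`GenotypeMatrix`.

    ``markers_in`` selects the table orientation (``"rows"`` or
    ``"columns"``).  Calls that are neither valid genotypes nor recognised
    missing tokens become missing, with the count logged.  Duplicate marker
    or sample ids, or markers absent from the map, are hard errors.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str)
    if markers_in == "columns":
        raw = raw.T
    elif markers_in != "rows":
        raise ValueError("markers_in must be 'rows' or 'columns'")
    gm = GenotypeMatrix.from_strings(raw, sample_meta)
    if gmap is not None:
        gm.validate_against(gmap)
    return gm


def read_founders(path, gmap: GeneticMap | None = None) -> FounderGenotypes:
    """Read founder-strain allele calls (tokens A/B; het or junk -> missing)."""
    raw = pd.read_csv(path, index_col=0, dtype=str)
    codes, n_bad, n_het = _parse_founder_tokens(raw)
    if n_het:
        logger.warning("%d heterozygous founder calls treated as missing", n_het)
    if n_bad:
        logger.warning("%d unparseable founder calls set to missing", n_bad)
    fg = FounderGenotypes(codes)
    if gmap is not None:
        missing = fg.marker_ids.difference(gmap.marker_ids)
        if len(missing):
            raise ValueError(f"{len(missing)} founder markers absent from map")
    return fg


def read_intensities(x_path, y_path) -> IntensityMatrix:
    x = pd.read_csv(x_path, index_col=0)
    y = pd.read_csv(y_path, index_col=0)
    return IntensityMatrix(x, y)


def read_control_file(path) -> DatasetBundle:
    """Load a dataset from a YAML control file naming the component CSVs.

    Recognised keys: ``geno``, ``founder_geno``, ``gmap``, ``covar`` and
    (optionally) ``intensities: {x: ..., y: ...}``.  Paths are resolved
    relative to the control file.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        return base / p

    gmap = read_map(resolve(cfg["gmap"]))
    meta = read_sample_meta(resolve(cfg["covar"])) if cfg.get("covar") else None
    gm = read_genotypes(resolve(cfg["geno"]), gmap, sample_meta=meta)
    founders = read_founders(resolve(cfg["founder_geno"]), gmap)
    intens = None
    if cfg.get("intensities"):
        intens = read_intensities(
            resolve(cfg["intensities"]["x"]), resolve(cfg["intensities"]["y"])
        )
    return DatasetBundle(gm, founders, gmap, intens)


def write_map(gmap: GeneticMap, path) -> None:
    out = gmap.table.rename(columns={"chromosome": "chr", "position_cM": "pos"})
    out.rename_axis("marker").to_csv(path)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    gm.to_strings().rename_axis("marker").to_csv(path)


def write_founders(fg: FounderGenotypes, path) -> None:
    fg.to_strings().rename_axis("marker").to_csv(path)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    out = meta.rename(columns={"nominal_sex": "sex"}).rename_axis("id")
    out.to_csv(path)


def write_intensities(intens: IntensityMatrix, x_path, y_path) -> None:
    intens.x.rename_axis("marker").to_csv(x_path)
    intens.y.rename_axis("marker").to_csv(y_path)


def write_control_file(path, *, geno, founder_geno, gmap, covar=None, intensities=None) -> None:
    cfg = {"geno": str(geno), "founder_geno": str(founder_geno), "gmap": str(gmap)}
    if covar:
        cfg["covar"] = str(covar)
    if intensities:
        cfg["intensities"] = {"x": str(intensities[0]), "y": str(intensities[1])}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# recoding and founder-based marker classification
# ---------------------------------------------------------------------------


@dataclass
class RecodeReport:
    """Bookkeeping from nucleotide -> A/B recoding."""

    excluded_multiallelic: list[str] = field(default_factory=list)
    monomorphic: list[str] = field(default_factory=list)
    n_unparseable: int = 0


def recode_to_founder_major(
    raw_calls: pd.DataFrame, raw_founders: pd.DataFrame
) -> tuple[GenotypeMatrix, FounderGenotypes, RecodeReport]:
    """Recode raw nucleotide calls to AA/AB/BB with A the founder-major allele.

    ``raw_calls`` holds two-letter nucleotide pairs (markers x samples) and
    ``raw_founders`` single-letter nucleotide calls (markers x 8 founders).
    The allele observed in more founder strains becomes A; when the two
    alleles are equally frequent among the (non-missing) founders the
    alphabetically first nucleotide becomes A.  Markers with more than two
    alleles across founders and samples are excluded and reported;
    monomorphic-in-founders markers are kept but flagged non-informative.
    """
    if not raw_calls.index.equals(raw_founders.index):
        raw_founders = raw_founders.reindex(raw_calls.index)
    report = RecodeReport()
    geno = np.full(raw_calls.shape, GENO_NA, dtype=np.int8)
    fall = np.full(raw_founders.shape, ALLELE_NA, dtype=np.int8)
    keep = np.ones(raw_calls.shape[0], dtype=bool)

    call_vals = raw_calls.to_numpy(dtype=object)
    fndr_vals = raw_founders.to_numpy(dtype=object)

    def clean(tok):
        if tok is None or (isinstance(tok, float) and np.isnan(tok)):
            return ""
        return str(tok).strip().upper()

    for i, marker in enumerate(raw_calls.index):
        f_tokens = [clean(t) for t in fndr_vals[i]]
        s_tokens = [clean(t) for t in call_vals[i]]
        alleles: dict[str, int] = {}
        for t in f_tokens:
            if t in NUCLEOTIDES:
                alleles[t] = alleles.get(t, 0) + 1
            elif t and t not in MISSING_TOKENS:
                report.n_unparseable += 1
        observed = set(alleles)
        for t in s_tokens:
            if t in MISSING_TOKENS or not t:
                continue
            if len(t) == 2 and all(ch in NUCLEOTIDES for ch in t):
                observed |= set(t)
            else:
                report.n_unparseable += 1
        if len(observed) > 2:
            keep[i] = False
            report.excluded_multiallelic.append(marker)
            continue
        if len(alleles) == 0:
            # no founder information: leave everything missing
            report.monomorphic.append(marker)
            continue
        if len(alleles) == 1:
            report.monomorphic.append(marker)
            major = next(iter(alleles))
            minor = next((x for x in sorted(observed) if x != major), None)
        else:
            (a1, n1), (a2, n2) = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
            major, minor = (a1, a2)  # tie broken alphabetically by the sort key
        for j, t in enumerate(f_tokens):
            if t == major:
                fall[i, j] = ALLELE_A
            elif minor is not None and t == minor:
                fall[i, j] = ALLELE_B
        for j, t in enumerate(s_tokens):
            if len(t) != 2 or any(ch not in NUCLEOTIDES for ch in t):
                continue
            n_minor = 0
            ok = True
            for ch in t:
                if ch == major:
                    pass
                elif minor is not None and ch == minor:
                    n_minor += 1
                else:
                    ok = False
            if ok:
                geno[i, j] = (GENO_AA, GENO_AB, GENO_BB)[n_minor]
    if report.n_unparseable:
        logger.warning("%d unparseable nucleotide tokens during recode", report.n_unparseable)

    idx = raw_calls.index[keep]
    gm = GenotypeMatrix(pd.DataFrame(geno[keep], index=idx, columns=raw_calls.columns))
    fg = FounderGenotypes(pd.DataFrame(fall[keep], index=idx, columns=raw_founders.columns))
    return gm, fg, report


def filter_informative(founders: FounderGenotypes) -> pd.Index:
    """Markers at which both alleles are observed among non-missing founders."""
    arr = founders.calls.to_numpy()
    has_a = (arr == ALLELE_A).any(axis=1)
    has_b = (arr == ALLELE_B).any(axis=1)
    return founders.marker_ids[has_a & has_b]


def founder_maf_class(founders: FounderGenotypes, marker: str | None = None):
    """Minor-allele count of each marker among the 8 founder strains.

    Returns an ``Int64`` series (or a scalar for a single ``marker``) with
    values 1-4 for markers with complete founder genotypes, 0 for
    complete-but-monomorphic markers, and missing (``pd.NA``) for markers
    where at least one founder call is missing ("incomplete").
    """
    arr = founders.calls.to_numpy()
    n_a = (arr == ALLELE_A).sum(axis=1)
    n_b = (arr == ALLELE_B).sum(axis=1)
    complete = (n_a + n_b) == N_FOUNDERS
    minor = np.minimum(n_a, n_b)
    out = pd.array(minor, dtype="Int64")
    out[~complete] = pd.NA
    series = pd.Series(out, index=founders.marker_ids, name="maf_class")
    if marker is not None:
        return series.loc[marker]
    return series


def maf_class_expected_freqs(maf_class: int) -> tuple[float, float, float]:
    """Expected (f_AA, f_AB, f_BB) under equal founder dosage for a MAF class.

    With minor-allele frequency ``m = maf_class / 8`` and the two haplotypes
    drawn independently and uniformly from the founders, the genotype
    frequencies follow Hardy-Weinberg proportions: major homozygote
    ``(1-m)^2``, heterozygote ``2m(1-m)``, minor homozygote ``m^2``.
    """
    if not 1 <= int(maf_class) <= 4:
        raise ValueError("MAF class must be 1..4")
    m = maf_class / N_FOUNDERS
    return ((1.0 - m) ** 2, 2.0 * m * (1.0 - m), m**2)


__all__ = [
    "GENO_NA",
    "GENO_AA",
    "GENO_AB",
    "GENO_BB",
    "GENO_LABELS",
    "ALLELE_NA",
    "ALLELE_A",
    "ALLELE_B",
    "N_FOUNDERS",
    "FOUNDER_LABELS",
    "MISSING_TOKENS",
    "GeneticMap",
    "GenotypeMatrix",
    "FounderGenotypes",
    "IntensityMatrix",
    "DatasetBundle",
    "RecodeReport",
    "read_map",
    "read_genotypes",
    "read_founders",
    "read_intensities",
    "read_sample_meta",
    "read_control_file",
    "write_map",
    "write_genotypes",
    "write_founders",
    "write_intensities",
    "write_sample_meta",
    "write_control_file",
    "recode_to_founder_major",
    "filter_informative",
    "founder_maf_class",
    "maf_class_expected_freqs",
]
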
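"""Genotype/phenotype containers, file readers, and reference-candidate splitting.

Genotypes are biallelic SNPs coded as 0/1/2 copies of one allele, one row per
animal, one column per SNP.  Markers carry a map (id, chromosome, physical
position) and are kept sorted by (chromosome, position); the antedependence
samplers rely on that ordering and on knowing where chromosomes start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "PhenotypeData",
    "GenotypeCodingError",
    "MapFormatError",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "read_phenotypes",
    "allele_frequencies",
    "chromosome_boundaries",
    "split_reference_candidate",
    "ReferenceCandidateSplit",
]


class GenotypeCodingError(ValueError):
    """An entry of the genotype matrix is not 0, 1, or 2 (or NA where allowed)."""


class MapFormatError(ValueError):
    """Marker map is malformed (wrong columns, duplicate positions, ...)."""


def _chrom_sort_key(labels):
    """Sort chromosome labels numerically when possible, else lexicographically."""

    def key(lab):
        s = str(lab)
        try:
            return (0, float(s), "")
        except ValueError:
            return (1, 0.0, s)

    return key


@dataclass
class GenotypeData:
    """0/1/2-coded marker matrix with marker map and animal ids.

    markers : (n_animals, n_markers) array with entries in {0, 1, 2}
    marker_ids, chromosome, position : per-marker map, sorted by
        (chromosome, position) with strictly increasing position per chromosome
    animal_ids : per-row identifiers
    """

    markers: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    animal_ids: np.ndarray

    def __post_init__(self):
        self.markers = np.asarray(self.markers)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self):
        n, m = self.markers.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        for name, arr in (
            ("marker_ids", self.marker_ids),
            ("chromosome", self.chromosome),
            ("position", self.position),
        ):
            if len(arr) != m:
                raise MapFormatError(f"{name} has length {len(arr)}, expected {m}")
        bad = ~np.isin(self.markers, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeCodingError(
                f"genotype entry {self.markers[i, j]!r} at animal "
                f"{self.animal_ids[i]!r} (row {i}), marker "
                f"{self.marker_ids[j]!r} (column {j}) is not 0/1/2"
            )
        # markers must be grouped by chromosome with strictly increasing positions
        seen = set()
        prev_chrom = None
        for j in range(m):
            c = self.chromosome[j]
            if c != prev_chrom:
                if c in seen:
                    raise MapFormatError(f"chromosome {c!r} appears in two blocks")
                seen.add(c)
                prev_chrom = c
            elif self.position[j] <= self.position[j - 1]:
                if self.position[j] == self.position[j - 1]:
                    raise MapFormatError(
                        f"duplicate position {self.position[j]} on chromosome {c!r}"
                    )
                raise MapFormatError(
                    f"markers out of positional order on chromosome {c!r} "
                    f"at column {j}"
                )

    # -- basic views ------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    def subset_animals(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            self.markers[idx], self.marker_ids, self.chromosome,
            self.position, self.animal_ids[idx],
        )

    def subset_markers(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            self.markers[:, idx], self.marker_ids[idx], self.chromosome[idx],
            self.position[idx], self.animal_ids,
        )

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chromosome": self.chromosome,
             "position": self.position}
        )


@dataclass
class PhenotypeData:
    """Response vector with a fixed-effect design.

    The intercept is included exactly once: if ``fixed_design`` lacks a
    constant column one is prepended.  X must have full column rank.
    """

    y: np.ndarray
    fixed_design: np.ndarray = None
    fixed_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        n = self.y.size
        if self.fixed_design is None:
            self.fixed_design = np.ones((n, 1))
            self.fixed_labels = ["intercept"]
        else:
            X = np.atleast_2d(np.asarray(self.fixed_design, dtype=np.float64))
            if X.shape[0] != n:
                raise ValueError(f"design has {X.shape[0]} rows for {n} phenotypes")
            const = [k for k in range(X.shape[1]) if np.ptp(X[:, k]) == 0 and X[0, k] != 0]
            if not const:
                X = np.column_stack([np.ones(n), X])
                self.fixed_labels = ["intercept"] + list(self.fixed_labels)
            elif len(const) > 1:
                raise ValueError("more than one constant column in the fixed design")
            self.fixed_design = X
            if not self.fixed_labels:
                self.fixed_labels = [f"fixed{k}" for k in range(X.shape[1])]
        if np.linalg.matrix_rank(self.fixed_design) < self.fixed_design.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    @property
    def n_animals(self) -> int:
        return self.y.size

    def subset(self, idx) -> "PhenotypeData":
        idx = np.asarray(idx)
        p = PhenotypeData.__new__(PhenotypeData)
        p.y = self.y[idx]
        p.fixed_design = self.fixed_design[idx]
        p.fixed_labels = list(self.fixed_labels)
        return p


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_map(path) -> pd.DataFrame:
    """Read a 3-column whitespace map file: marker_id, chromosome, position."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] != 3:
        raise MapFormatError(f"map file {path} has {df.shape[1]} columns, expected 3")
    df.columns = ["marker_id", "chromosome", "position"]
    try:
        df["position"] = df["position"].astype(np.int64)
    except ValueError as e:
        raise MapFormatError(f"non-integer position in map file {path}: {e}") from e
    return df


def _sorted_map_order(mapdf: pd.DataFrame):
    key = _chrom_sort_key(mapdf["chromosome"])
    order = sorted(
        range(len(mapdf)),
        key=lambda j: (key(mapdf["chromosome"].iloc[j]), mapdf["position"].iloc[j]),
    )
    return np.asarray(order)


def read_genotypes(path, dialect: str = "matrix", map_path=None, ids_path=None) -> GenotypeData:
    """Read genotypes in the plain ``matrix`` or PLINK ``plink_raw`` dialect.

    ``matrix``: whitespace 0/1/2 matrix, animals in rows; missing values are a
    hard error.  ``plink_raw``: PLINK --recode A output (FID IID PAT MAT SEX
    PHENOTYPE then one column per SNP); NA entries are mean-imputed per SNP
    (rounded to the nearest 0/1/2) with a logged count.  Both dialects need a
    3-column map file; markers are re-sorted by (chromosome, position) with a
    warning if the map is out of order.
    """
    if map_path is None:
        raise MapFormatError("a marker map file is required")
    mapdf = read_map(map_path)

    if dialect == "matrix":
        raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        vals = raw.to_numpy()
        ok = np.isin(vals, ("0", "1", "2"))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeCodingError(
                f"entry {vals[i, j]!r} at row {i}, column {j} of {path} is not 0/1/2"
            )
        markers = vals.astype(np.int8)
        if ids_path is not None:
            animal_ids = np.loadtxt(ids_path, dtype=str).astype(object).ravel()
            if animal_ids.size != markers.shape[0]:
                raise ValueError(
                    f"{animal_ids.size} animal ids for {markers.shape[0]} genotype rows"
                )
        else:
            animal_ids = np.array(
                [f"A{i + 1}" for i in range(markers.shape[0])], dtype=object
            )
        snp_names = None
    elif dialect == "plink_raw":
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in PLINK_RAW_META if c not in raw.columns]
        if missing_meta:
            raise MapFormatError(
                f"plink_raw file {path} lacks header columns {missing_meta}"
            )
        snp_cols = [c for c in raw.columns if c not in PLINK_RAW_META]
        animal_ids = raw["IID"].to_numpy(dtype=object)
        vals = raw[snp_cols].to_numpy()
        markers = np.empty(vals.shape, dtype=np.float64)
        is_na = (vals == "NA") | pd.isna(vals)
        ok = np.isin(vals, ("0", "1", "2")) | is_na
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeCodingError(
                f"entry {vals[i, j]!r} for animal {animal_ids[i]!r}, SNP "
                f"{snp_cols[j]!r} of {path} is not 0/1/2/NA"
            )
        markers[~is_na] = vals[~is_na].astype(np.float64)
        markers[is_na] = np.nan
        n_imputed = int(is_na.sum())
        if n_imputed:
            col_mean = np.nanmean(np.where(is_na, np.nan, markers), axis=0)
            col_mean = np.nan_to_num(col_mean)  # all-NA column -> 0
            fill = np.clip(np.rint(col_mean), 0, 2)
            idx = np.argwhere(is_na)
            markers[idx[:, 0], idx[:, 1]] = fill[idx[:, 1]]
            logger.info("mean-imputed %d missing genotypes in %s", n_imputed, path)
        markers = markers.astype(np.int8)
        # strip PLINK allele suffix SNP_A -> SNP for map matching
        snp_names = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    if markers.shape[1] != len(mapdf):
        raise MapFormatError(
            f"{markers.shape[1]} genotype columns but {len(mapdf)} map rows"
        )
    if snp_names is not None and list(mapdf["marker_id"]) != snp_names:
        # allow map in any order: align by marker id
        pos = {mid: k for k, mid in enumerate(mapdf["marker_id"])}
        unknown = [s for s in snp_names if s not in pos]
        if unknown:
            raise MapFormatError(f"SNPs absent from map: {unknown[:5]}")
        mapdf = mapdf.iloc[[pos[s] for s in snp_names]].reset_index(drop=True)

    # duplicate positions within a chromosome are a format error
    dup = mapdf.duplicated(subset=["chromosome", "position"])
    if dup.any():
        r = mapdf[dup].iloc[0]
        raise MapFormatError(
            f"duplicate position {r['position']} on chromosome {r['chromosome']!r}"
        )

    order = _sorted_map_order(mapdf)
    if not np.array_equal(order, np.arange(len(mapdf))):
        logger.warning(
            "markers in %s were not sorted by (chromosome, position); re-sorting",
            map_path,
        )
        mapdf = mapdf.iloc[order].reset_index(drop=True)
        markers = markers[:, order]

    return GenotypeData(
        markers=markers,
        marker_ids=mapdf["marker_id"].to_numpy(dtype=object),
        chromosome=mapdf["chromosome"].to_numpy(dtype=object),
        position=mapdf["position"].to_numpy(),
        animal_ids=animal_ids,
    )


def write_genotypes(g: GenotypeData, path, dialect: str = "matrix", map_path=None):
    """Write genotypes (and optionally the map) in a readable dialect."""
    if dialect == "matrix":
        np.savetxt(path, g.markers, fmt="%d")
    elif dialect == "plink_raw":
        df = pd.DataFrame(
            {"FID": g.animal_ids, "IID": g.animal_ids, "PAT": 0, "MAT": 0,
             "SEX": 0, "PHENOTYPE": -9}
        )
        geno = pd.DataFrame(g.markers, columns=[f"{m}_A" for m in g.marker_ids])
        pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if map_path is not None:
        g.map_frame().to_csv(map_path, sep=" ", index=False, header=False)


def read_phenotypes(path, animal_ids=None, design_path=None) -> PhenotypeData:
    """Read a 2-column (id, value) phenotype file, aligned to ``animal_ids``.

    With no design file the model is intercept-only (pre-corrected phenotypes).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["id", "value"], dtype={"id": str})
    df["value"] = df["value"].astype(np.float64)
    if animal_ids is not None:
        lut = dict(zip(df["id"], df["value"]))
        missing = [a for a in animal_ids if str(a) not in lut]
        if missing:
            raise ValueError(f"phenotypes missing for animals {missing[:5]}")
        y = np.array([lut[str(a)] for a in animal_ids])
    else:
        y = df["value"].to_numpy()
    X = None
    if design_path is not None:
        X = np.loadtxt(design_path, ndmin=2)
    return PhenotypeData(y=y, fixed_design=X)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeData) -> np.ndarray:
    """Frequency p_k of the counted allele per SNP: column sum / 2n."""
    return g.markers.sum(axis=0) / (2.0 * g.n_animals)


def chromosome_boundaries(g: GenotypeData) -> np.ndarray:
    """Column indices at which each chromosome block starts (first is 0)."""
    chrom = g.chromosome
    starts = [0]
    for j in range(1, len(chrom)):
        if chrom[j] != chrom[j - 1]:
            starts.append(j)
    return np.asarray(starts, dtype=np.int64)


@dataclass
class ReferenceCandidateSplit:
    reference_geno: GenotypeData
    reference_pheno: PhenotypeData
    candidate_geno: GenotypeData
    candidate_pheno: PhenotypeData
    reference_idx: np.ndarray
    candidate_idx: np.ndarray


def split_reference_candidate(
    g: GenotypeData, p: PhenotypeData, fraction: float = 0.5, seed: int = 0
) -> ReferenceCandidateSplit:
    """Randomly partition animals into reference (training) and candidate sets.

    Reference size is floor(fraction*n + 0.5); the candidate set takes the
    remainder.  A fixed seed gives an identical partition.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = g.n_animals
    if n < 2:
        raise ValueError("need at least 2 animals to split")
    if p.n_animals != n:
        raise ValueError("genotypes and phenotypes disagree on animal count")
    n_ref = int(np.floor(fraction * n + 0.5))
    n_ref = min(max(n_ref, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ref_idx = np.sort(perm[:n_ref])
    cand_idx = np.sort(perm[n_ref:])
    return ReferenceCandidateSplit(
        reference_geno=g.subset_animals(ref_idx),
        reference_pheno=p.subset(ref_idx),
        candidate_geno=g.subset_animals(cand_idx),
        candidate_pheno=p.subset(cand_idx),
        reference_idx=ref_idx,
        candidate_idx=cand_idx,
    )
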
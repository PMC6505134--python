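"""Readers and writers for genotype/phenotype/map tables, plus packaged
transcriptions of the published B73-Zd and Zd-RF phenotype tables.

Two genotype dialects are supported:

``numeric123``
    TSV/CSV with plants as rows and markers as columns, cells coded
    1 (Zd homozygote) / 2 (maize homozygote) / 3 (heterozygote), missing as
    ``-``/``NA``/empty.  Marker chromosome and position come from a sidecar
    map file (marker_id, chromosome, position_bp).

``acgt_vcf``
    A minimal VCF (v4.x) reader over biallelic GT-only records.  By default
    REF is taken as the Zd allele and the single ALT as the maize allele;
    pass ``zd_is_ref=False`` to flip the parent assignment.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (AA, AB, BB, MISSING, CALL_TO_NUMERIC, DataError,
                        GenotypeMatrix, MarkerLocus, NUMERIC_TO_CALL,
                        NUMERIC_TO_STATUS, PhenotypeTable,
                        chromosome_sort_key)

log = logging.getLogger(__name__)

MISSING_TOKENS = {"-", "--", "NA", "N", ".", ""}
_HEADER_COMMENT = f"# regrowqtl v{__version__}"


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_map_file(path: str | Path) -> list[MarkerLocus]:
    """Read a marker map table (marker_id, chromosome, position_bp)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"marker_id", "chromosome", "position_bp"}
    if not need.issubset(df.columns):
        raise DataError(f"map file {path}: columns {sorted(need)} required, "
                        f"found {list(df.columns)}")
    return [MarkerLocus(str(r.chromosome), int(r.position_bp), str(r.marker_id))
            for r in df.itertuples()]


def write_map_file(markers: Iterable[MarkerLocus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        fh.write("marker_id\tchromosome\tposition_bp\n")
        for mk in markers:
            fh.write(f"{mk.id}\t{mk.chromosome}\t{mk.position_bp}\n")


def _parse_numeric_cell(token: str, row: str, col: str) -> int:
    token = token.strip()
    if token in MISSING_TOKENS:
        return MISSING
    try:
        code = int(token)
    except ValueError:
        raise DataError(f"genotype cell {token!r} at plant {row!r}, "
                        f"marker {col!r} is not a valid code") from None
    if code not in NUMERIC_TO_CALL:
        raise DataError(f"genotype code {code} at plant {row!r}, marker "
                        f"{col!r} outside {{1,2,3,missing}}")
    return NUMERIC_TO_CALL[code]


def read_genotype_table(path: str | Path, dialect: str = "numeric123",
                        map_path: str | Path | None = None,
                        zd_is_ref: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix in either supported dialect.

    For ``numeric123`` a sidecar ``map_path`` supplies marker coordinates;
    if omitted, a file next to ``path`` named ``<stem>.map.tsv`` is used.
    For ``acgt_vcf`` the VCF itself carries coordinates.
    """
    if dialect == "numeric123":
        return _read_numeric_table(Path(path), map_path)
    if dialect == "acgt_vcf":
        return read_vcf(path, zd_is_ref=zd_is_ref)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_numeric_table(path: Path,
                        map_path: str | Path | None) -> GenotypeMatrix:
    if map_path is None:
        map_path = path.with_suffix("").with_suffix("")  # strip one suffix
        map_path = path.parent / (path.stem + ".map.tsv")
    markers = {mk.id: mk for mk in read_map_file(map_path)}
    delim = _sniff_delimiter(path)
    with open(path, encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim)
                if r and not r[0].startswith("#")]
    if not rows:
        raise DataError(f"{path}: empty genotype table")
    header = [c.strip() for c in rows[0]]
    if len(header) < 2 or header[0] == "":
        raise DataError(f"{path}: malformed header (first column must name "
                        "the plant-id column, then marker ids)")
    marker_ids = header[1:]
    if len(set(marker_ids)) != len(marker_ids):
        raise DataError(f"{path}: duplicate marker ids in header")
    unknown = [m for m in marker_ids if m not in markers]
    if unknown:
        raise DataError(f"{path}: markers missing from map file: "
                        f"{unknown[:5]}")
    plants, calls = [], []
    for r in rows[1:]:
        if len(r) != len(header):
            raise DataError(f"{path}: row {r[0]!r} has {len(r)} fields, "
                            f"expected {len(header)}")
        plants.append(r[0].strip())
        calls.append([_parse_numeric_cell(tok, r[0], col)
                      for tok, col in zip(r[1:], marker_ids)])
    loci = [markers[m] for m in marker_ids]
    order = sorted(range(len(loci)),
                   key=lambda j: (chromosome_sort_key(loci[j].chromosome),
                                  loci[j].position_bp))
    loci = [loci[j] for j in order]
    arr = np.asarray(calls, dtype=np.int8)[:, order]
    return GenotypeMatrix(plants, loci, arr)


def write_genotype_table(g: GenotypeMatrix, path: str | Path,
                         map_path: str | Path | None = None) -> None:
    """Write the numeric123 dialect plus its sidecar map file."""
    path = Path(path)
    if map_path is None:
        map_path = path.parent / (path.stem + ".map.tsv")
    write_map_file(g.markers, map_path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        fh.write("plant\t" + "\t".join(g.marker_ids()) + "\n")
        for i, plant in enumerate(g.plants):
            toks = ["-" if c == MISSING else str(CALL_TO_NUMERIC[int(c)])
                    for c in g.calls[i]]
            fh.write(plant + "\t" + "\t".join(toks) + "\n")


def read_vcf(path: str | Path, zd_is_ref: bool = True) -> GenotypeMatrix:
    """Minimal VCF reader: biallelic sites, GT field only."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    plants = list(vcf.samples)
    loci, cols = [], []
    hom_ref, hom_alt = (AA, BB) if zd_is_ref else (BB, AA)
    lut = np.array([hom_ref, AB, hom_alt, MISSING], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(f"VCF site {var.CHROM}:{var.POS} is not "
                            "biallelic (ALT alleles: %s)" % (var.ALT,))
        loci.append(MarkerLocus(str(var.CHROM), int(var.POS),
                                var.ID or f"S{var.CHROM}_{var.POS}"))
        cols.append(lut[var.gt_types])
    if not loci:
        raise DataError(f"{path}: no variant records")
    arr = np.stack(cols, axis=1)
    order = sorted(range(len(loci)),
                   key=lambda j: (chromosome_sort_key(loci[j].chromosome),
                                  loci[j].position_bp))
    return GenotypeMatrix(plants, [loci[j] for j in order], arr[:, order])


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a two-column (plant, status) table; accepts R/NR or 1/2 coding."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    statuses: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim)
                if r and not r[0].startswith("#")]
    if rows and [c.strip().lower() for c in rows[0][:2]] in (
            ["plant", "phenotype"], ["plant", "status"], ["plant", "pt"]):
        rows = rows[1:]
    for r in rows:
        if len(r) < 2:
            raise DataError(f"{path}: phenotype row {r!r} needs 2 columns")
        plant, tok = r[0].strip(), r[1].strip()
        if plant in statuses:
            raise DataError(f"{path}: duplicate plant id {plant!r}")
        statuses[plant] = _parse_status(tok, path, plant)
    if not statuses:
        log.warning("%s: empty phenotype table", path)
    return PhenotypeTable(statuses)


def _parse_status(tok: str, path, plant: str) -> str:
    up = tok.upper()
    if up in ("R", "NR"):
        return up
    if tok in ("1", "2"):
        return NUMERIC_TO_STATUS[int(tok)]
    raise DataError(f"{path}: status {tok!r} for plant {plant!r} outside "
                    "{R, NR, 1, 2}")


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        fh.write("plant\tphenotype\n")
        for plant, status in p.items():
            fh.write(f"{plant}\t{status}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> _io.StringIO:
    txt = (resources.files("regrowqtl") / "data" / name).read_text("utf-8")
    return _io.StringIO(txt)


def load_b73_zd_f2() -> pd.DataFrame:
    """B73 x Z. diploperennis F2 phenotypes with gt1/tb1/id1 genotypes.

    Columns: plant, role (parent|f2), gbs (bool: used for GBS SNP calling),
    phenotype (R/NR), gt1/tb1/id1 (numeric codes as strings, '-' missing).
    """
    df = pd.read_csv(_data_text("b73_zd_f2_phenotypes.tsv"), sep="\t",
                     comment="#", dtype=str)
    df["gbs"] = df["gbs"].astype(int).astype(bool)
    return df


def b73_zd_f2_phenotypes(gbs_only: bool = False) -> PhenotypeTable:
    df = load_b73_zd_f2()
    df = df[df.role == "f2"]
    if gbs_only:
        df = df[df.gbs]
    return PhenotypeTable(dict(zip(df.plant, df.phenotype)))


def load_zd_rf() -> pd.DataFrame:
    """Zd x Rhee Flint F2/F3 phenotypes (plant, generation, phenotype)."""
    return pd.read_csv(_data_text("zd_rf_phenotypes.tsv"), sep="\t",
                       comment="#", dtype=str)


def zd_rf_phenotypes(generation: str = "f2") -> PhenotypeTable:
    df = load_zd_rf()
    df = df[df.generation == generation]
    if df.empty:
        raise KeyError(f"unknown Zd-RF generation {generation!r}")
    return PhenotypeTable(dict(zip(df.plant, df.phenotype)))


def load_segregation_counts() -> pd.DataFrame:
    """Published per-generation regrowth segregation counts."""
    df = pd.read_csv(_data_text("segregation_counts.tsv"), sep="\t",
                     comment="#")
    return df.astype({"total": int, "n_R": int, "n_NR": int})
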
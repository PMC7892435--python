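"""Data model and I/O for STR marker maps and phased haplotype sets.

The canonical interchange formats are two small TSV dialects:

* marker map: ``marker  side  dist_cM  repeat_unit  mu`` — one STR locus per
  row, with ``side`` giving the position relative to the disease mutation
  (``proximal`` or ``distal``) and ``dist_cM`` the genetic distance from it.
* haplotypes: ``chrom_id  family_id  group  independent  <marker...>`` — one
  phased chromosome per row, integer repeat numbers, ``NA`` for missing.

PED/MAP import is supported for convenience; **PED files are normally
unphased** — here the two allele columns per locus are taken at face value
as two already-phased chromosomes, which is only correct if the PED was
written from phased data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

SIDES = ("proximal", "distal")
GROUPS = ("carrier", "control")
MISSING = "NA"


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class MarkerInfo:
    """One STR locus flanking the disease mutation."""

    name: str
    side: str
    dist_cM: float
    repeat_unit: int
    mu: float
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r} for marker {self.name}")
        if not self.dist_cM > 0:
            raise ValueError(f"non-positive distance for marker {self.name}: {self.dist_cM}")
        if not 0 <= self.mu < 1:
            raise ValueError(f"mutation rate out of [0, 1) for marker {self.name}: {self.mu}")
        if self.repeat_unit not in (2, 3, 4, 5, 6):
            raise ValueError(f"implausible repeat unit for marker {self.name}: {self.repeat_unit}")
        if self.theta is not None and not 0 <= self.theta <= 1:
            raise ValueError(f"theta out of [0, 1] for marker {self.name}: {self.theta}")

    def with_theta(self, theta: float) -> "MarkerInfo":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered collection of markers, sorted outward per side."""

    markers: tuple[MarkerInfo, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker map must contain at least one marker")
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate marker name(s): {sorted(dupes)}")
        object.__setattr__(
            self,
            "markers",
            tuple(sorted(self.markers, key=lambda m: (SIDES.index(m.side), m.dist_cM))),
        )
        for side in SIDES:
            dists = [m.dist_cM for m in self.side_markers(side)]
            if len(set(dists)) != len(dists):
                raise ValueError(f"markers on the {side} side share a dist_cM value")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def side_markers(self, side: str) -> list[MarkerInfo]:
        """Markers on one side, ordered outward (increasing dist_cM)."""
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        return sorted((m for m in self.markers if m.side == side), key=lambda m: m.dist_cM)

    def __getitem__(self, name: str) -> MarkerInfo:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class ChromosomeRecord:
    """One phased chromosome: repeat number per marker, or None if missing.

    Carrier records represent the mutation-bearing chromosome only; the
    ``independent`` flag marks chromosomes counted in unrelated-chromosome
    statistics (one per family, typically).
    """

    chrom_id: str
    family_id: str
    group: str
    independent: bool
    alleles: Mapping[str, Optional[int]]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for chromosome {self.chrom_id}")
        for name, a in self.alleles.items():
            if a is not None and (not isinstance(a, int) or a <= 0):
                raise ValueError(
                    f"allele at {name} on chromosome {self.chrom_id} must be a "
                    f"positive integer or missing, got {a!r}"
                )


@dataclass(frozen=True)
class HaplotypeSet:
    """A marker map plus the phased chromosomes typed on it."""

    map: MarkerMap
    records: tuple[ChromosomeRecord, ...]

    def __post_init__(self) -> None:
        names = set(self.map.names)
        for rec in self.records:
            if set(rec.alleles) != names:
                raise ValueError(
                    f"chromosome {rec.chrom_id} alleles do not cover the marker map"
                )

    def carriers(self, independent_only: bool = False) -> list[ChromosomeRecord]:
        return [
            r
            for r in self.records
            if r.group == "carrier" and (r.independent or not independent_only)
        ]

    def controls(self) -> list[ChromosomeRecord]:
        return [r for r in self.records if r.group == "control"]


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker-map TSV; theta is left unset until conversion."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"marker", "side", "dist_cM", "repeat_unit", "mu"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"{path}: marker map header must contain {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        markers: list[MarkerInfo] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            name = row["marker"].strip()
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate marker name {name!r}")
            seen.add(name)
            try:
                markers.append(
                    MarkerInfo(
                        name=name,
                        side=row["side"].strip(),
                        dist_cM=float(row["dist_cM"]),
                        repeat_unit=int(row["repeat_unit"]),
                        mu=float(row["mu"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not markers:
        raise ParseError(f"{path}: no marker rows")
    return MarkerMap(tuple(markers))


def _parse_allele(token: str, path: Path, lineno: int, col: str) -> Optional[int]:
    token = token.strip()
    if token == MISSING or token == "":
        return None
    try:
        value = int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: column {col!r}: allele must be an integer or NA, got {token!r}"
        ) from None
    if value <= 0:
        raise ParseError(f"{path}:{lineno}: column {col!r}: allele must be positive, got {value}")
    return value


def _read_haplotypes_tsv(path: Path, marker_map: MarkerMap) -> HaplotypeSet:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        meta = ["chrom_id", "family_id", "group", "independent"]
        marker_cols = [c for c in reader.fieldnames if c not in meta]
        if reader.fieldnames[:4] != meta:
            raise ParseError(f"{path}: header must start with {meta}")
        if set(marker_cols) != set(marker_map.names):
            raise ParseError(
                f"{path}: marker columns {marker_cols} do not match map {marker_map.names}"
            )
        records: list[ChromosomeRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if row["independent"] not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: independent must be 0 or 1")
            alleles = {
                c: _parse_allele(row[c], path, lineno, c) for c in marker_cols
            }
            try:
                records.append(
                    ChromosomeRecord(
                        chrom_id=row["chrom_id"],
                        family_id=row["family_id"],
                        group=row["group"],
                        independent=row["independent"] == "1",
                        alleles=alleles,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return HaplotypeSet(marker_map, tuple(records))


def _read_haplotypes_pedmap(path: Path, marker_map: MarkerMap) -> HaplotypeSet:
    """PED + MAP import; each individual's two allele columns per locus are
    taken as two already-phased chromosomes (see module docstring caveat)."""
    map_path = path.with_suffix(".map")
    order: list[str] = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}")
            order.append(fields[1])
    if set(order) != set(marker_map.names):
        raise ParseError(f"{map_path}: loci {order} do not match map {marker_map.names}")
    records: list[ChromosomeRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(order):
                raise ParseError(
                    f"{path}:{lineno}: expected {6 + 2 * len(order)} columns, got {len(fields)}"
                )
            fam, iid, _, _, _, pheno = fields[:6]
            if pheno not in ("1", "2"):
                raise ParseError(f"{path}:{lineno}: phenotype must be 1 (control) or 2 (carrier)")
            group = "carrier" if pheno == "2" else "control"
            for hap in (0, 1):
                alleles: dict[str, Optional[int]] = {}
                for k, name in enumerate(order):
                    token = fields[6 + 2 * k + hap]
                    alleles[name] = (
                        None if token == "0" else _parse_allele(token, path, lineno, name)
                    )
                records.append(
                    ChromosomeRecord(
                        chrom_id=f"{iid}_{hap + 1}",
                        family_id=fam,
                        group=group,
                        independent=True,
                        alleles=alleles,
                    )
                )
    if not records:
        raise ParseError(f"{path}: empty PED file")
    return HaplotypeSet(marker_map, tuple(records))


def read_haplotypes(
    path: str | Path, marker_map: MarkerMap, dialect: str = "tsv"
) -> HaplotypeSet:
    """Read phased chromosomes; ``dialect`` is ``tsv`` or ``pedmap``."""
    path = Path(path)
    if dialect == "tsv":
        return _read_haplotypes_tsv(path, marker_map)
    if dialect == "pedmap":
        return _read_haplotypes_pedmap(path, marker_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_haplotypes(hapset: HaplotypeSet, path: str | Path) -> None:
    """Write the canonical wide TSV; read_haplotypes inverts it exactly."""
    path = Path(path)
    names = hapset.map.names
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom_id", "family_id", "group", "independent", *names])
        for rec in hapset.records:
            writer.writerow(
                [
                    rec.chrom_id,
                    rec.family_id,
                    rec.group,
                    "1" if rec.independent else "0",
                    *[MISSING if rec.alleles[n] is None else rec.alleles[n] for n in names],
                ]
            )


def _data_path(filename: str):
    return resources.files("founderage.data").joinpath(filename)


def paper_marker_map() -> MarkerMap:
    """The packaged 8-marker map flanking the disease locus."""
    with resources.as_file(_data_path("markers_atbp3.tsv")) as p:
        return read_marker_map(p)


def packaged_delta_table() -> dict[str, float]:
    """Published per-marker LD index values (delta), keyed by marker name."""
    out: dict[str, float] = {}
    with _data_path("table1_delta.tsv").open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["marker"]] = float(row["delta"])
    return out
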
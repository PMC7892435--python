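"""Allele frequencies, ancestral-haplotype inference and LD index values.

The LD index per marker is delta = (p_D - p_N) / (1 - p_N), where p_D is the
frequency of the ancestral allele set on mutation-bearing chromosomes and
p_N the same frequency on control chromosomes (Bengtsson-Thomson).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .haplotype_io import GROUPS, HaplotypeSet

log = logging.getLogger(__name__)


class EmptyGroupError(ValueError):
    """No usable chromosomes in the requested group at a marker."""


class UndefinedDeltaError(ValueError):
    """delta is undefined because the control frequency is 1."""


@dataclass(frozen=True)
class AncestralHaplotype:
    """Per marker, the non-empty set of ancestral repeat numbers.

    Usually a singleton per marker; two alleles may co-occur when the carrier
    chromosomes are split between adjacent states (e.g. a recombination or
    one-step mutation close to the disease locus early in the genealogy).
    """

    alleles: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        for name, s in self.alleles.items():
            if not s:
                raise ValueError(f"empty ancestral allele set at marker {name}")
        object.__setattr__(
            self, "alleles", {k: frozenset(v) for k, v in self.alleles.items()}
        )

    def __getitem__(self, name: str) -> frozenset[int]:
        return self.alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.alleles


def allele_frequencies(
    hapset: HaplotypeSet,
    group: str,
    marker: str,
    independent_only: bool = True,
) -> tuple[dict[int, float], int]:
    """Frequency table (repeat number -> proportion) in one group at one marker.

    Returns the table and the number of chromosomes with a non-missing allele.
    Missing alleles are excluded marker-wise.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if group == "carrier":
        recs = hapset.carriers(independent_only=independent_only)
    else:
        recs = hapset.controls()
    observed = [r.alleles[marker] for r in recs if r.alleles[marker] is not None]
    if not observed:
        raise EmptyGroupError(f"no usable {group} chromosomes at marker {marker}")
    counts = Counter(observed)
    n = len(observed)
    return {a: c / n for a, c in sorted(counts.items())}, n


def infer_ancestral(
    hapset: HaplotypeSet,
    near_tie_frac: float = 0.8,
    strict_modal: bool = False,
) -> AncestralHaplotype:
    """Modal repeat number per marker among independent carrier chromosomes.

    If the runner-up count reaches ``near_tie_frac`` of the modal count the
    marker gets a two-allele ancestral set (this is what produces a bi-allelic
    state at a locus tightly linked to the mutation). With ``strict_modal``
    the set is always a singleton; exact ties resolve to the smallest repeat
    number.
    """
    carriers = hapset.carriers(independent_only=True)
    if not carriers:
        raise EmptyGroupError("no independent carrier chromosomes")
    alleles: dict[str, frozenset[int]] = {}
    for name in hapset.map.names:
        observed = [r.alleles[name] for r in carriers if r.alleles[name] is not None]
        if not observed:
            raise EmptyGroupError(f"all independent carriers missing at marker {name}")
        counts = Counter(observed)
        # ties broken toward the smaller repeat number for determinism
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        modal_allele, modal_count = ranked[0]
        chosen = {modal_allele}
        if not strict_modal and len(ranked) > 1:
            runner_allele, runner_count = ranked[1]
            if runner_count >= near_tie_frac * modal_count:
                chosen.add(runner_allele)
        alleles[name] = frozenset(chosen)
    return AncestralHaplotype(alleles)


def ancestral_proportion(
    hapset: HaplotypeSet,
    anc: AncestralHaplotype,
    marker: str,
    independent_only: bool = True,
) -> tuple[float, int, int]:
    """Proportion of carrier chromosomes bearing an ancestral allele.

    Returns (proportion, count, denominator).
    """
    carriers = hapset.carriers(independent_only=independent_only)
    observed = [r.alleles[marker] for r in carriers if r.alleles[marker] is not None]
    if not observed:
        raise EmptyGroupError(f"no usable carrier chromosomes at marker {marker}")
    count = sum(1 for a in observed if a in anc[marker])
    return count / len(observed), count, len(observed)


def compute_delta(
    hapset: HaplotypeSet,
    anc: AncestralHaplotype,
    independent_only: bool = True,
) -> pd.DataFrame:
    """Per-marker LD index table.

    Columns: p_D, p_N, delta, n_D, n_N, informative. Frequencies are of the
    ancestral allele *set* (summed over set members). Markers with
    delta <= 0 are retained but flagged non-informative.
    """
    rows = []
    for name in hapset.map.names:
        anc_set = anc[name]
        freq_d, n_d = allele_frequencies(
            hapset, "carrier", name, independent_only=independent_only
        )
        freq_n, n_n = allele_frequencies(hapset, "control", name, independent_only=False)
        p_d = sum(freq_d.get(a, 0.0) for a in anc_set)
        p_n = sum(freq_n.get(a, 0.0) for a in anc_set)
        if p_n >= 1.0:
            raise UndefinedDeltaError(
                f"delta undefined at marker {name}: ancestral set fixed in controls"
            )
        delta = (p_d - p_n) / (1.0 - p_n)
        if delta <= 0:
            log.warning("marker %s has non-positive delta (%.4f); non-informative", name, delta)
        rows.append(
            {
                "marker": name,
                "p_D": p_d,
                "p_N": p_n,
                "delta": delta,
                "n_D": n_d,
                "n_N": n_n,
                "informative": delta > 0,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def write_delta(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def read_ancestral(path: str | Path) -> AncestralHaplotype:
    """Read an ancestral haplotype TSV: ``marker  alleles`` with ``/``-joined sets."""
    alleles: dict[str, frozenset[int]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            alleles[row["marker"]] = frozenset(int(t) for t in row["alleles"].split("/"))
    if not alleles:
        raise ValueError(f"{path}: no ancestral haplotype rows")
    return AncestralHaplotype(alleles)


def paper_ancestral_haplotype() -> AncestralHaplotype:
    """The packaged fully conserved ancestral haplotype of the study."""
    with resources.as_file(
        resources.files("founderage.data").joinpath("ancestral_atbp3.tsv")
    ) as p:
        return read_ancestral(p)
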
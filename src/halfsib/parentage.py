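"""Microsatellite support: allele frequencies, Probability of Identity,
multilocus-genotype uniqueness and exclusion-based paternity.

These computations underpin the half-sib design: the sires must be
distinct, effectively unrelated individuals (checked via multilocus
genotype uniqueness and the Probability of Identity), and each
genotyped larva must be traced back to its sire from the presence of
sire alleles at the typed loci.

Per-locus PI is the standard unbiased-naive statistic for unrelated
individuals, PI = 2(sum p_i^2)^2 - sum p_i^4; loci are assumed
independent so the multilocus PI is the product over loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


class EmptyLocusError(ValueError):
    """No non-missing diploid call at the locus."""


class InvalidFrequencyError(ValueError):
    """Allele frequencies do not sum to one."""


@dataclass
class GenotypeTable:
    """Diploid allele-size calls, samples x loci.

    ``data`` is a wide DataFrame indexed by sample with two integer
    columns per locus (``<locus>_a``, ``<locus>_b``); a missing call has
    both alleles NaN (a half-missing call is invalid).
    """

    data: pd.DataFrame
    loci: tuple[str, ...]

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "GenotypeTable":
        df = df.copy()
        if "sample" in df.columns:
            df = df.set_index("sample")
        pairs = [c[:-2] for c in df.columns if c.endswith("_a")]
        loci = tuple(l for l in pairs if f"{l}_b" in df.columns)
        if not loci:
            raise ValueError("no '<locus>_a'/'<locus>_b' column pairs found")
        cols = [c for l in loci for c in (f"{l}_a", f"{l}_b")]
        df = df[cols].apply(pd.to_numeric, errors="coerce")
        for locus in loci:
            a, b = df[f"{locus}_a"], df[f"{locus}_b"]
            half = a.isna() ^ b.isna()
            if half.any():
                bad = df.index[half].tolist()
                raise ValueError(f"half-missing diploid call at locus {locus} for {bad}")
            present = a.dropna()
            if ((present <= 0) | (present % 1 != 0)).any() or (
                (b.dropna() <= 0) | (b.dropna() % 1 != 0)
            ).any():
                raise ValueError(f"allele sizes at {locus} must be positive integers")
        return cls(df, loci)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    def call(self, sample, locus) -> tuple[int, int] | None:
        """The unordered allele pair for one sample at one locus, or None."""
        a = self.data.at[sample, f"{locus}_a"]
        b = self.data.at[sample, f"{locus}_b"]
        if pd.isna(a):
            return None
        return (int(min(a, b)), int(max(a, b)))


@dataclass
class PaternityCall:
    """Exclusion-based assignment outcome for one offspring."""

    sample_id: str
    status: str  # assigned | unassigned-multiple | unassigned-none | excluded-low-amplification
    sire_id: str | None
    n_loci_amplified: int
    compatible_sires: list


def allele_frequencies(genotypes: GenotypeTable, locus: str) -> dict[int, float]:
    """Allele frequencies at a locus; each diploid call contributes two copies."""
    if locus not in genotypes.loci:
        raise KeyError(f"unknown locus {locus!r}")
    alleles: Counter = Counter()
    for sample in genotypes.samples:
        call = genotypes.call(sample, locus)
        if call is not None:
            alleles.update(call)
    total = sum(alleles.values())
    if total == 0:
        raise EmptyLocusError(f"locus {locus} has no non-missing calls")
    return {a: c / total for a, c in sorted(alleles.items())}


def probability_of_identity(freqs: dict[int, float]) -> float:
    """PI = 2(sum p^2)^2 - sum p^4: chance two random unrelated individuals
    share a genotype at this locus under Hardy-Weinberg proportions."""
    p = np.asarray(list(freqs.values()), dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise InvalidFrequencyError("allele frequencies must be nonnegative and sum to 1")
    return float(2.0 * (p**2).sum() ** 2 - (p**4).sum())


def per_locus_pi(genotypes: GenotypeTable, loci=None) -> dict[str, float]:
    """Per-locus PI values computed from the table's own allele frequencies."""
    loci = tuple(loci) if loci is not None else genotypes.loci
    return {l: probability_of_identity(allele_frequencies(genotypes, l)) for l in loci}


def combined_pi(genotypes: GenotypeTable, loci=None) -> float:
    """Product of per-locus PI values (loci assumed independent)."""
    values = per_locus_pi(genotypes, loci)
    return float(np.prod(list(values.values())))


def unique_mlg(genotypes: GenotypeTable, missing_as_wildcard: bool = False) -> list[list]:
    """Group samples by exact multilocus genotype.

    Allele pairs are compared unordered.  A missing locus mismatches
    every call unless ``missing_as_wildcard`` is set, in which case it
    matches anything (samples are then grouped greedily in input order).
    """
    samples = genotypes.samples
    profiles = {
        s: tuple(genotypes.call(s, l) for l in genotypes.loci) for s in samples
    }
    if not missing_as_wildcard:
        groups: dict = {}
        for s in samples:
            groups.setdefault(profiles[s], []).append(s)
        return list(groups.values())

    def matches(p, q):
        return all(a is None or b is None or a == b for a, b in zip(p, q))

    groups_list: list[list] = []
    for s in samples:
        for grp in groups_list:
            if all(matches(profiles[s], profiles[t]) for t in grp):
                grp.append(s)
                break
        else:
            groups_list.append([s])
    return groups_list


def _locus_compatible(off_call, sire_call, dam_call=None) -> bool:
    """Presence/absence rule: the sire must carry at least one offspring allele.

    With a known dam genotype the rule is Mendelian: the offspring pair
    must be partitionable into one allele carried by the sire and one by
    the dam.
    """
    if dam_call is None:
        return off_call[0] in sire_call or off_call[1] in sire_call
    a, b = off_call
    return (a in sire_call and b in dam_call) or (b in sire_call and a in dam_call)


def assign_paternity(
    offspring: GenotypeTable,
    sires: GenotypeTable,
    min_loci: int = 3,
    dam: dict[str, tuple[int, int]] | None = None,
) -> list[PaternityCall]:
    """Exclusion-based paternity for each offspring against a sire panel.

    A sire is compatible when, at every locus where the offspring
    amplified, it carries at least one of the offspring's alleles.
    Offspring amplifying at fewer than ``min_loci`` loci (default 3,
    i.e. strictly more than 2) are excluded; exactly one compatible sire
    yields an assignment.  ``dam`` optionally supplies the dam's
    genotype per locus for the stricter Mendelian rule.
    """
    loci = [l for l in sires.loci if l in offspring.loci]
    for sire in sires.samples:
        for locus in loci:
            if sires.call(sire, locus) is None:
                raise ValueError(f"sire {sire} is missing a call at {locus}")
    calls = []
    for off in offspring.samples:
        typed = [l for l in loci if offspring.call(off, l) is not None]
        if len(typed) < min_loci:
            calls.append(PaternityCall(off, "excluded-low-amplification", None, len(typed), []))
            continue
        compatible = [
            sire
            for sire in sires.samples
            if all(
                _locus_compatible(
                    offspring.call(off, l),
                    sires.call(sire, l),
                    None if dam is None else dam.get(l),
                )
                for l in typed
            )
        ]
        if len(compatible) == 1:
            status, sire_id = "assigned", compatible[0]
        elif compatible:
            status, sire_id = "unassigned-multiple", None
        else:
            status, sire_id = "unassigned-none", None
        calls.append(PaternityCall(off, status, sire_id, len(typed), compatible))
    return calls
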
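"""Strain-mixture detection from the within-sample allele-frequency
spectrum.

A sample dominated by one strain shows minor-allele frequencies near 0
at essentially every site (sequencing error only); a mixture of strains
shows a band of intermediate frequencies at their divergent sites. The
statistic here is the fraction of eligible sites (depth-qualified,
monomorphic sites included with frequency 0) whose minor-allele
frequency falls in an intermediate band, defaulting to [0.10, 0.50].

Because the denominator is the whole eligible genome, the expected
fraction for a mixture is roughly (between-strain divergence) × (band
capture probability), while a single strain sits at the sequencing-
error noise floor (~1e-4 at error rate 0.001 with Q30 filtering and
20×). The default call cutoff of 0.002 sits an order of magnitude above
that floor and detects mixtures down to ~0.2% divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import write_tsv

DEFAULT_BAND = (0.10, 0.50)
DEFAULT_MIN_SITE_DEPTH = 10
DEFAULT_MIN_SITES = 100
DEFAULT_CUTOFF = 0.002
#: an in-band site must carry at least this many minor-allele reads;
#: a single-read minor (e.g. freq exactly 0.10 at depth 10) is
#: indistinguishable from one sequencing error and would otherwise put
#: ~1% of minimum-depth sites in the band at error rate 1e-3
DEFAULT_MIN_MINOR_SUPPORT = 2

SINGLE = "single_dominant"
MIXTURE = "mixture"
INSUFFICIENT = "insufficient_data"


@dataclass
class MixtureCall:
    species_id: str
    sample_id: str
    n_eligible_sites: int
    intermediate_fraction: float
    call: str


def intermediate_fraction(
    site_records: Iterable[tuple[int, float]],
    min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
    band: tuple[float, float] = DEFAULT_BAND,
    min_minor_support: int = DEFAULT_MIN_MINOR_SUPPORT,
) -> tuple[int, float]:
    """(n_eligible, fraction in band) over (depth, minor_freq) records.

    Eligible sites have depth >= min_site_depth; monomorphic sites count
    toward the denominator with frequency 0. The band is a closed
    interval on minor-allele frequency within [0, 0.5]; an in-band site
    additionally needs at least ``min_minor_support`` minor reads.
    """
    lo, hi = band
    if not 0 <= lo < hi <= 0.5:
        raise ValueError("band must satisfy 0 <= lo < hi <= 0.5")
    n_eligible = 0
    n_band = 0
    for depth, minor_freq in site_records:
        if depth < min_site_depth:
            continue
        n_eligible += 1
        if lo <= minor_freq <= hi and minor_freq * depth >= min_minor_support - 0.5:
            n_band += 1
    return n_eligible, (n_band / n_eligible if n_eligible else 0.0)


def classify_mixture(
    fraction: float,
    n_eligible: int,
    species_id: str = "",
    sample_id: str = "",
    min_sites: int = DEFAULT_MIN_SITES,
    cutoff: float = DEFAULT_CUTOFF,
) -> MixtureCall:
    """Binary call: mixture when the intermediate fraction reaches the cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if n_eligible < min_sites:
        call = INSUFFICIENT
    elif fraction >= cutoff:
        call = MIXTURE
    else:
        call = SINGLE
    return MixtureCall(species_id, sample_id, n_eligible, fraction, call)


def sites_from_pileup(pileup_path: str | Path) -> dict[str, list[tuple[int, float]]]:
    """Per-species (depth, minor-allele frequency) records from a
    single-sample pileup TSV. Minor frequency is 1 − major frequency of
    the two top alleles, i.e. second-largest count / depth."""
    df = pd.read_csv(str(pileup_path), sep="\t", dtype={"species_id": str})
    out: dict[str, list[tuple[int, float]]] = {}
    counts = df[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    for i, row in enumerate(df.itertuples(index=False)):
        c = sorted(counts[i], reverse=True)
        depth = int(sum(c))
        minor_freq = c[1] / depth if depth else 0.0
        out.setdefault(row.species_id, []).append((depth, float(minor_freq)))
    return out


def call_sample(
    pileup_path: str | Path,
    sample_id: str,
    min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
    band: tuple[float, float] = DEFAULT_BAND,
    min_sites: int = DEFAULT_MIN_SITES,
    cutoff: float = DEFAULT_CUTOFF,
    min_minor_support: int = DEFAULT_MIN_MINOR_SUPPORT,
) -> list[MixtureCall]:
    """All species-level mixture calls for one sample's pileup."""
    calls = []
    for sid, recs in sorted(sites_from_pileup(pileup_path).items()):
        n, frac = intermediate_fraction(recs, min_site_depth, band, min_minor_support)
        calls.append(classify_mixture(frac, n, sid, sample_id, min_sites, cutoff))
    return calls


def write_calls(path: str | Path, calls: list[MixtureCall]) -> None:
    write_tsv(
        path,
        ["species_id", "sample_id", "n_eligible_sites", "intermediate_fraction", "call"],
        [
            [c.species_id, c.sample_id, c.n_eligible_sites, c.intermediate_fraction, c.call]
            for c in calls
        ],
    )
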
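"""Gene-flow quantities from homologous-recombination event lists.

Turns recombination tracts (e.g. Gubbins predictions) into within- and
between-lineage genome fractions, per-strain r/m and rho/theta, and
divergence probabilities with speciation-stage labels. The divergence
probability of a lineage pair is the genome fraction *resistant* to
between-lineage gene flow, ``P_div = 1 - fraction_between`` (union mode, so
the fraction is a true proportion), used as a proxy staging quantity along
the speciation continuum.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import RecombEvent, SnpAlignment


# ---------------------------------------------------------------------------
# Event attribution
# ---------------------------------------------------------------------------

def attribute_events(
    events: Sequence[RecombEvent],
    lineage_map: Mapping[str, str],
    strict: bool = True,
) -> list[dict]:
    """Categorize each event as within-lineage or between-lineage.

    An event whose carriers all fall in one lineage is ``within`` that
    lineage (single-carrier terminal-branch events included, flagged); an
    event intersecting k >= 2 lineages contributes a ``between`` record for
    every pair of intersected lineages (events are counted repeatedly, the
    shared-and-unique counting convention).
    """
    out = []
    for ev in events:
        unknown = [c for c in ev.carriers if c not in lineage_map]
        if unknown:
            if strict:
                raise KeyError(f"unknown carriers {sorted(unknown)}")
            warnings.warn(f"dropping unknown carriers {sorted(unknown)}")
        lins = sorted({lineage_map[c] for c in ev.carriers if c in lineage_map})
        if not lins:
            continue
        if len(lins) == 1:
            out.append({
                "event": ev, "kind": "within", "lineages": (lins[0],),
                "terminal": len(ev.carriers) == 1,
            })
        else:
            for a, b in itertools.combinations(lins, 2):
                out.append({
                    "event": ev, "kind": "between", "lineages": (a, b),
                    "terminal": False,
                })
    return out


# ---------------------------------------------------------------------------
# Genome fractions
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, (cs, ce) = 0, intervals[0]
    for s, e in intervals[1:]:
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            total += ce - cs + 1
            cs, ce = s, e
    return total + ce - cs + 1


@dataclass
class GeneFlowMatrix:
    fraction_within: dict[str, float]
    fraction_between: dict[tuple[str, str], float]
    mode: str  # "summed" or "union"


def geneflow_fractions(
    events: Sequence[RecombEvent],
    lineage_map: Mapping[str, str],
    genome_length: int,
    mode: str = "summed",
) -> GeneFlowMatrix:
    """Genome fraction subject to recombination, per lineage and lineage pair.

    ``summed`` counts every event length (overlaps repeatedly, so fractions
    may exceed 1); ``union`` measures the length of the interval union
    (always <= 1). Both agree when events are disjoint.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if mode not in ("summed", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    for ev in events:
        if ev.end > genome_length:
            raise ValueError(f"event {ev.start}-{ev.end} exceeds genome bounds")
    attributed = attribute_events(events, lineage_map)
    lineages = sorted(set(lineage_map.values()))
    within: dict[str, list[tuple[int, int]]] = {lin: [] for lin in lineages}
    between: dict[tuple[str, str], list[tuple[int, int]]] = {
        pair: [] for pair in itertools.combinations(lineages, 2)
    }
    for rec in attributed:
        iv = (rec["event"].start, rec["event"].end)
        if rec["kind"] == "within":
            within[rec["lineages"][0]].append(iv)
        else:
            between[rec["lineages"]].append(iv)

    def measure(ivs: list[tuple[int, int]]) -> float:
        if mode == "summed":
            return sum(e - s + 1 for s, e in ivs) / genome_length
        return _union_length(ivs) / genome_length

    return GeneFlowMatrix(
        fraction_within={lin: measure(ivs) for lin, ivs in within.items()},
        fraction_between={p: measure(ivs) for p, ivs in between.items()},
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Per-strain r/m and rho/theta
# ---------------------------------------------------------------------------

@dataclass
class StrainRecombSummary:
    sample_id: str
    lineage: str
    rm: float
    rho_theta: float
    frac_recombined: float
    n_events: int
    snps_inside: int
    snps_outside: int


def strain_recomb_params(
    events: Sequence[RecombEvent],
    aln: SnpAlignment,
    sample_id: str,
    lineage_map: Mapping[str, str],
) -> StrainRecombSummary:
    """r/m and rho/theta for one strain from its events and its SNPs.

    A strain's SNPs are its alternate-allele calls against the reference;
    r/m = SNPs inside the union of its tracts / SNPs outside; rho/theta =
    number of its events / SNPs outside.
    """
    if sample_id not in aln.sample_ids:
        raise KeyError(f"no SNP data for sample {sample_id!r}")
    row = aln.genotypes[aln.sample_ids.index(sample_id)]
    snp_pos = aln.positions[row == 1]
    own = [ev for ev in events if sample_id in ev.carriers]
    ivs = [(ev.start, ev.end) for ev in own]
    inside = np.zeros(len(snp_pos), dtype=bool)
    for s, e in ivs:
        inside |= (snp_pos >= s) & (snp_pos <= e)
    n_in = int(inside.sum())
    n_out = int(len(snp_pos) - n_in)
    if n_out == 0:
        warnings.warn(f"{sample_id}: no SNPs outside recombination tracts")
        rm = math.nan if n_in > 0 else 0.0
        rho_theta = math.nan if own else 0.0
    else:
        rm = n_in / n_out
        rho_theta = len(own) / n_out
    return StrainRecombSummary(
        sample_id=sample_id,
        lineage=lineage_map.get(sample_id, ""),
        rm=rm,
        rho_theta=rho_theta,
        frac_recombined=_union_length(ivs) / aln.genome_length,
        n_events=len(own),
        snps_inside=n_in,
        snps_outside=n_out,
    )


def all_strain_recomb_params(
    events: Sequence[RecombEvent],
    aln: SnpAlignment,
    lineage_map: Mapping[str, str],
) -> list[StrainRecombSummary]:
    return [
        strain_recomb_params(events, aln, sid, lineage_map)
        for sid in aln.sample_ids
    ]


def lineage_recomb_comparison(
    summaries: Sequence[StrainRecombSummary],
    grouping: str = "lineage",
    stat: str = "rho_theta",
    groups_of: Mapping[str, str] | None = None,
):
    """Kruskal-Wallis + Dunn comparison of a recombination statistic between
    lineages (or any grouping, e.g. habitat, via ``groups_of``)."""
    from .eco_geo_stats import dunn_posthoc, kruskal_wallis

    groups: dict[str, list[float]] = {}
    for s in summaries:
        key = groups_of.get(s.sample_id, "") if groups_of else getattr(s, grouping)
        val = getattr(s, stat)
        if key and np.isfinite(val):
            groups.setdefault(key, []).append(val)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >=2 groups with >=2 members")
    h, p = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups)
    return {"H": h, "p": p, "dunn": dunn}


# ---------------------------------------------------------------------------
# Divergence-probability staging
# ---------------------------------------------------------------------------

@dataclass
class UpcelResult:
    pair: tuple[str, str]
    p_div: float
    stage: str  # "species (4-5)" | "grey zone (2-3)" | "early (1-2)"


DEFAULT_STAGE_THRESHOLDS = (0.89, 0.85)  # (species >=, grey zone >=)


def upcel_stages(
    matrix: GeneFlowMatrix,
    thresholds: tuple[float, float] = DEFAULT_STAGE_THRESHOLDS,
) -> list[UpcelResult]:
    """Divergence probability and speciation stage per lineage pair.

    ``P_div = 1 - fraction_between`` (clamped to [0, 1]); the stage labels
    are presentation thresholds, not inference: species at P_div >= the
    first threshold, grey zone down to the second, early below.
    """
    if not thresholds[0] > thresholds[1]:
        raise ValueError("stage thresholds must be descending")
    if matrix.mode != "union":
        warnings.warn(
            "P_div computed from non-union fractions; clamping to [0, 1]"
        )
    out = []
    for pair in sorted(matrix.fraction_between):
        p_div = min(1.0, max(0.0, 1.0 - matrix.fraction_between[pair]))
        if p_div >= thresholds[0]:
            stage = "species (4-5)"
        elif p_div >= thresholds[1]:
            stage = "grey zone (2-3)"
        else:
            stage = "early (1-2)"
        out.append(UpcelResult(pair=pair, p_div=p_div, stage=stage))
    return out
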
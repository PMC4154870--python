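"""Multi-screen hit triage.

After the primary screen and RSA ranking, candidate genes pass through
three further layers, each an SD-margin rule against the non-targeting
control distribution of its own screen arm:

* **Validation screen** (same reporter assay, elicitor stimulus, two
  re-synthesized siRNAs per gene): an siRNA is an inhibiting hit iff its
  inhibition-oriented median z exceeds the control median by strictly more
  than ``validation_sd`` (2.0) control SDs. The gene-level call uses the
  strongest siRNA by default (the gene list is ranked by the strongest
  siRNA's median z); requiring both siRNAs is available via
  ``ScreenConfig.gene_hit_rule = "both"``.
* **Counter screen** (TNF stimulus, pathway-independent): genes called by
  the same rule on the TNF arm respond to NF-kB perturbation generally, not
  to the receptor pathway, and are excluded.
* **THP1 screen** (myeloid reporter line, SEAP/XTT dual readout): a gene is
  an inhibiting hit iff two siRNAs exceed 1.5 control SDs; a strong hit if
  additionally at least one exceeds 3.0 SDs.

The final shortlist is the intersection of validation and THP1 hits minus
the counter-screen exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import InsufficientControlsError, ScreenConfig

STATUS_NONE = "none"
STATUS_HIT = "inhibiting_hit"
STATUS_STRONG = "strong_inhibiting_hit"


@dataclass(frozen=True)
class ControlStats:
    """Location/spread of the non-targeting-control score distribution."""

    median: float
    sd: float


@dataclass(frozen=True)
class HitCall:
    gene_id: str
    screen: str  # hek_validation | hek_counter_tnf | thp1
    status: str
    evidence: str  # per-siRNA median z values and the thresholds applied


@dataclass(frozen=True)
class TriageResult:
    """Gene sets of every triage layer plus the final intersected shortlist."""

    primary_ranked: tuple[str, ...]
    validation_hits: frozenset[str]
    tnf_excluded: frozenset[str]
    nod1_specific: frozenset[str]
    thp1_hits: frozenset[str]
    thp1_strong: frozenset[str]
    confirmed_both: frozenset[str]
    final_shortlist: frozenset[str]
    calls: tuple[HitCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.final_shortlist <= self.confirmed_both <= self.validation_hits:
            raise ValueError("final ⊆ confirmed ⊆ validation violated")
        if not self.thp1_strong <= self.thp1_hits:
            raise ValueError("thp1_strong ⊆ thp1_hits violated")
        if self.nod1_specific & self.tnf_excluded:
            raise ValueError("nod1_specific and tnf_excluded overlap")

    def flow_counts(self) -> dict[str, int]:
        """Per-stage gene counts for the screening flow-chart report."""
        return {
            "primary_ranked": len(self.primary_ranked),
            "validation_hits": len(self.validation_hits),
            "nod1_specific": len(self.nod1_specific),
            "thp1_hits": len(self.thp1_hits),
            "thp1_strong": len(self.thp1_strong),
            "confirmed_both": len(self.confirmed_both),
            "final_shortlist": len(self.final_shortlist),
        }


def _sirna_hits(
    scores: pd.DataFrame, ctrl: ControlStats, sd_margin: float
) -> pd.Series:
    """Strict SD-margin rule on inhibition-oriented median z-scores."""
    if ctrl is None or not (ctrl.sd == ctrl.sd):  # NaN guard
        raise InsufficientControlsError("control statistics required for hit calls")
    return scores["median_z"] > ctrl.median + sd_margin * ctrl.sd


def call_validation_hits(
    scores: pd.DataFrame,
    ctrl: ControlStats,
    config: ScreenConfig,
    screen: str = "hek_validation",
) -> tuple[list[HitCall], set[str]]:
    """Validation-screen hit calls from a per-siRNA median-z table.

    ``scores`` needs columns gene_id, sirna_id, median_z (two siRNAs per
    gene in the validation design). Returns the per-gene calls and the hit
    gene set. Boundary behaviour is strict: a z exactly at
    ``median + 2 SD`` is not a hit.
    """
    scored = scores[scores["median_z"].notna()]
    is_hit = _sirna_hits(scored, ctrl, config.thresholds.validation_sd)
    calls: list[HitCall] = []
    hits: set[str] = set()
    for gene_id, grp in scored.groupby("gene_id", sort=True):
        gene_hits = is_hit.loc[grp.index]
        if config.gene_hit_rule == "strongest":
            gene_is_hit = bool(gene_hits.any())
        else:  # "both": every scored siRNA must qualify
            gene_is_hit = bool(gene_hits.all()) and len(grp) >= 2
        status = STATUS_HIT if gene_is_hit else STATUS_NONE
        evidence = (
            "z=" + ";".join(f"{z:.4g}" for z in grp["median_z"])
            + f" rule>{config.thresholds.validation_sd}SD"
            + f" ctrl_median={ctrl.median:.4g} ctrl_sd={ctrl.sd:.4g}"
        )
        calls.append(HitCall(str(gene_id), screen, status, evidence))
        if gene_is_hit:
            hits.add(str(gene_id))
    return calls, hits


def exclude_counter_hits(
    validation_hits: set[str], tnf_hits: set[str]
) -> tuple[set[str], set[str]]:
    """Split validation hits into pathway-specific and counter-screen-excluded.

    Returns ``(nod1_specific, excluded)`` with
    ``nod1_specific | excluded == validation_hits``.
    """
    excluded = set(validation_hits) & set(tnf_hits)
    return set(validation_hits) - excluded, excluded


def call_thp1_hits(
    scores: pd.DataFrame,
    ctrl: ControlStats,
    config: ScreenConfig,
) -> tuple[list[HitCall], set[str], set[str]]:
    """THP1 dual-threshold hit calls.

    Inhibiting hit: two siRNAs of the gene exceed the control median by
    > ``thp1_sd`` (1.5) SDs. Strong inhibiting hit: additionally at least
    one siRNA exceeds ``thp1_strong_sd`` (3.0) SDs. Genes with fewer than
    two scored siRNAs cannot satisfy the two-siRNA rule and are flagged
    insufficient-data with status none.

    Returns (calls, hit gene set, strong-hit gene set).
    """
    scored = scores[scores["median_z"].notna()]
    pass_15 = _sirna_hits(scored, ctrl, config.thresholds.thp1_sd)
    pass_30 = _sirna_hits(scored, ctrl, config.thresholds.thp1_strong_sd)
    calls: list[HitCall] = []
    hits: set[str] = set()
    strong: set[str] = set()
    for gene_id, grp in scored.groupby("gene_id", sort=True):
        zs = ";".join(f"{z:.4g}" for z in grp["median_z"])
        if len(grp) < 2:
            calls.append(
                HitCall(str(gene_id), "thp1", STATUS_NONE, f"z={zs} insufficient-data")
            )
            continue
        n15 = int(pass_15.loc[grp.index].sum())
        n30 = int(pass_30.loc[grp.index].sum())
        if n15 >= 2:
            status = STATUS_STRONG if n30 >= 1 else STATUS_HIT
            hits.add(str(gene_id))
            if status == STATUS_STRONG:
                strong.add(str(gene_id))
        else:
            status = STATUS_NONE
        evidence = (
            f"z={zs} rule 2x>{config.thresholds.thp1_sd}SD"
            f" strong 1x>{config.thresholds.thp1_strong_sd}SD"
        )
        calls.append(HitCall(str(gene_id), "thp1", status, evidence))
    return calls, hits, strong


def intersect_final(
    primary_ranked: list[str],
    validation_hits: set[str],
    tnf_hits: set[str],
    thp1_hits: set[str],
    thp1_strong: set[str],
    calls: list[HitCall] | None = None,
) -> TriageResult:
    """Assemble the full triage result with all set-algebra invariants.

    ``confirmed_both`` is the intersection of the validation and THP1 hit
    sets; subtracting the counter-screen exclusions yields the final
    shortlist.
    """
    nod1_specific, excluded = exclude_counter_hits(validation_hits, tnf_hits)
    confirmed = frozenset(validation_hits) & frozenset(thp1_hits)
    final = confirmed - frozenset(excluded)
    return TriageResult(
        primary_ranked=tuple(primary_ranked),
        validation_hits=frozenset(validation_hits),
        tnf_excluded=frozenset(excluded),
        nod1_specific=frozenset(nod1_specific),
        thp1_hits=frozenset(thp1_hits),
        thp1_strong=frozenset(thp1_strong & set(thp1_hits)),
        confirmed_both=confirmed,
        final_shortlist=final,
        calls=tuple(calls or ()),
    )


def triage_frame(result: TriageResult) -> pd.DataFrame:
    """Gene-by-layer status table (the triage.tsv artifact)."""
    genes = sorted(
        set(result.primary_ranked)
        | result.validation_hits
        | result.thp1_hits
        | result.tnf_excluded
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "validation_hit": [g in result.validation_hits for g in genes],
            "tnf_excluded": [g in result.tnf_excluded for g in genes],
            "nod1_specific": [g in result.nod1_specific for g in genes],
            "thp1_hit": [g in result.thp1_hits for g in genes],
            "thp1_strong": [g in result.thp1_strong for g in genes],
            "confirmed_both": [g in result.confirmed_both for g in genes],
            "final_shortlist": [g in result.final_shortlist for g in genes],
        }
    )
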
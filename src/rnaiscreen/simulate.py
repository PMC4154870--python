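"""Seeded synthetic screens with known ground truth.

The generator emulates an arrayed dual-readout RNAi reporter screen:
genes x independent siRNAs in replicate on 384-well plates, every plate
carrying non-targeting, pathway-positive (p65), receptor-positive (NOD1)
and toxicity (PLK) control wells. The generative model per well is
multiplicative, because luminescence and absorbance are positive
multiplicative-error instruments:

    t   ~ LogNormal(mean 1, cv = transfection_cv)      transfection efficiency
    v   = t * (1 - toxicity loss)                      viable, transfected cells
    V   = plate_factor * v * eps_b                     viability readout
    a   = baseline * (1 - inhibition)                  reporter output per cell
    A   = plate_factor * t * a * eps_a                 activity readout

with eps mean-1 lognormal noise of configured CV and a per-plate lognormal
``plate_factor`` shared by both channels (so the activity/viability ratio
cancels it — the property the normalization cascade relies on). Inhibition
combines the siRNA's on-target knockdown (applied to planted inhibitor
genes in the elicitor arm; only shared-pathway genes respond in the TNF
arm) with any planted off-target effect as 1-(1-e_on)(1-e_off).

Artifact classes with known truth labels:

* planted inhibitor genes (all of their siRNAs on-target, effect drawn from
  ``effect_range``),
* toxic siRNAs (near-total viability loss; removed by the 40% well filter),
* decoy genes carried by exactly one strong off-target siRNA (removed by
  the <2-OPI-hit rule),
* optional additional random off-target siRNAs,
* per-plate multiplicative effects; gross plate failures are injected
  separately with :func:`inject_plate_artifacts`.

Randomness: one root seed; every plate draws from its own child stream
``numpy.random.default_rng([root_seed, STREAM_PLATE0 + plate_index])`` and
the truth tables from ``default_rng([root_seed, STREAM_TRUTH])``, so plate
subsets are reproducible in isolation and identical (config, seed) gives
bit-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import WELL_COLUMNS, ScreenConfig, format_well, plate_shape

STREAM_TRUTH = 1
STREAM_PLATE0 = 1000

CONTROL_SIRNAS = {
    "neg_ctrl": "ALLSTARS",
    "pos_ctrl_pathway": "SI_P65",
    "pos_ctrl_receptor": "SI_NOD1",
    "tox_ctrl": "SI_PLK",
}


class SimTruthSpec(BaseModel):
    """Ground-truth design of a synthetic screen.

    Defaults are the desk-scale study conditions: 500 genes with 25 planted
    inhibitors whose four siRNAs all carry >=70% knockdown, 15% measurement
    noise CV on both channels, 15% lognormal plate effects, ten decoy genes
    carried by a single strong off-target siRNA, and a 1% toxic-siRNA rate.
    Toxic and random off-target siRNAs are planted only on genes that are
    neither inhibitors nor decoys, keeping the planted truth classes
    disjoint and interpretable.
    """

    n_genes: int = Field(default=500, ge=1)
    n_inhibitors: int = Field(default=25, ge=0)
    effect_range: tuple[float, float] = (0.70, 0.95)
    shared_pathway_fraction: float = 0.2
    n_decoy_offtarget_genes: int = Field(default=10, ge=0)
    off_target_effect: float = 0.8
    extra_off_target_rate: float = 0.005
    toxic_sirna_rate: float = 0.01
    toxic_viability_loss: float = 0.9
    transfection_cv: float = 0.20
    noise_cv_activity: float = 0.15
    noise_cv_viability: float = 0.15
    plate_effect_sd: float = 0.15
    baseline_activity: float = 1000.0
    p65_effect: float = 0.90
    nod1_effect: float = 0.85
    tox_ctrl_viability_loss: float = 0.97

    @field_validator(
        "shared_pathway_fraction",
        "off_target_effect",
        "extra_off_target_rate",
        "toxic_sirna_rate",
        "toxic_viability_loss",
        "p65_effect",
        "nod1_effect",
        "tox_ctrl_viability_loss",
    )
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates and effect fractions must lie in [0, 1]")
        return v

    @field_validator("effect_range")
    @classmethod
    def _effect_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("effect_range must satisfy 0 <= lo <= hi <= 1")
        return v


@dataclass(frozen=True)
class ScreenDef:
    """One simulated screen arm: identifier, stimulus, replicate count."""

    screen_id: str
    stimulus: str
    replicates: int | None = None  # None -> config.replicates


#: The three-screen study plan: elicitor primary screen and TNF counter
#: screen in the reporter cell line, plus the myeloid (THP1) screen with
#: its three analysed replicates.
DEFAULT_PLAN = (
    ScreenDef("hek_tridap", "TriDAP"),
    ScreenDef("hek_tnf", "TNF"),
    ScreenDef("thp1", "TriDAP", replicates=3),
)


@dataclass
class SimTruth:
    """Ground truth of one simulated study, traceable per well.

    ``genes``: gene_id, true_effect, shared_pathway, decoy.
    ``sirnas``: sirna_id, gene_id, on_target, toxic, off_target_effect.
    ``plates``: plate_id, plate_factor.
    """

    genes: pd.DataFrame
    sirnas: pd.DataFrame
    plates: pd.DataFrame
    seed: int

    @property
    def inhibitors(self) -> set[str]:
        return set(self.genes.loc[self.genes["true_effect"] > 0, "gene_id"])

    @property
    def decoys(self) -> set[str]:
        return set(self.genes.loc[self.genes["decoy"], "gene_id"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.sirnas.to_csv(outdir / "truth_sirnas.tsv", sep="\t", index=False)
        self.plates.to_csv(outdir / "truth_plates.tsv", sep="\t", index=False)


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with exact mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def make_truth(config: ScreenConfig, spec: SimTruthSpec, seed: int) -> SimTruth:
    """Draw the gene/siRNA ground-truth tables (plate factors filled later)."""
    rng = np.random.default_rng([seed, STREAM_TRUTH])
    n = spec.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n)]

    effects = np.zeros(n)
    shared = np.zeros(n, bool)
    decoy = np.zeros(n, bool)
    special = rng.choice(n, size=spec.n_inhibitors + spec.n_decoy_offtarget_genes,
                         replace=False)
    inhibitor_idx = special[: spec.n_inhibitors]
    decoy_idx = special[spec.n_inhibitors:]
    lo, hi = spec.effect_range
    effects[inhibitor_idx] = rng.uniform(lo, hi, size=spec.n_inhibitors)
    n_shared = int(round(spec.shared_pathway_fraction * spec.n_inhibitors))
    shared[rng.permutation(inhibitor_idx)[:n_shared]] = True
    decoy[decoy_idx] = True

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_effect": effects,
            "shared_pathway": shared,
            "decoy": decoy,
        }
    )

    k = config.sirnas_per_gene
    sirna_gene = np.repeat(np.arange(n), k)
    sirna_ids = [f"{gene_ids[g]}_s{i % k + 1}" for i, g in enumerate(sirna_gene)]
    toxic = np.zeros(n * k, bool)
    off_eff = np.zeros(n * k)

    plain = ~(np.isin(sirna_gene, inhibitor_idx) | np.isin(sirna_gene, decoy_idx))
    toxic[plain] = rng.random(plain.sum()) < spec.toxic_sirna_rate
    eligible_off = plain & ~toxic
    off_eff[eligible_off & (rng.random(n * k) < spec.extra_off_target_rate)] = (
        spec.off_target_effect
    )
    # exactly one off-target siRNA per decoy gene (the first)
    for g in decoy_idx:
        off_eff[g * k] = spec.off_target_effect

    sirnas = pd.DataFrame(
        {
            "sirna_id": sirna_ids,
            "gene_id": [gene_ids[g] for g in sirna_gene],
            "on_target": ~toxic,  # toxic siRNAs kill rather than report
            "toxic": toxic,
            "off_target_effect": off_eff,
        }
    )
    plates = pd.DataFrame(columns=["plate_id", "plate_factor"])
    return SimTruth(genes=genes, sirnas=sirnas, plates=plates, seed=seed)


def _plate_layouts(config: ScreenConfig, sirnas: pd.DataFrame) -> list[pd.DataFrame]:
    """Split the siRNA library over plates, prefixing each plate's controls."""
    rows, cols = plate_shape(config.plate_format)
    all_wells = [format_well(r, c) for r in range(rows) for c in range(cols)]
    ctrl_rows = []
    for role, count in config.control_layout.items():
        ctrl_rows += [(CONTROL_SIRNAS[role], "", role)] * count
    n_ctrl = len(ctrl_rows)
    per_plate = config.plate_format - n_ctrl

    layouts = []
    records = list(zip(sirnas["sirna_id"], sirnas["gene_id"]))
    for start in range(0, len(records), per_plate):
        chunk = records[start : start + per_plate]
        plate = ctrl_rows + [(sid, gid, "sample") for sid, gid in chunk]
        layouts.append(
            pd.DataFrame(
                plate, columns=["sirna_id", "gene_id", "role"]
            ).assign(well=all_wells[: len(plate)])
        )
    return layouts


def _sirna_inhibition(
    truth: SimTruth, spec: SimTruthSpec, stimulus: str
) -> pd.Series:
    """Per-siRNA reporter inhibition fraction for one stimulus arm."""
    genes = truth.genes.set_index("gene_id")
    s = truth.sirnas
    effect = genes.loc[s["gene_id"], "true_effect"].to_numpy(float)
    if stimulus == "TNF":
        responds = genes.loc[s["gene_id"], "shared_pathway"].to_numpy(bool)
        effect = np.where(responds, effect, 0.0)
    e_on = np.where(s["on_target"].to_numpy(bool), effect, 0.0)
    e_off = s["off_target_effect"].to_numpy(float)
    return pd.Series(1.0 - (1.0 - e_on) * (1.0 - e_off), index=s["sirna_id"])


def simulate_screen(
    config: ScreenConfig,
    spec: SimTruthSpec,
    seed: int | None = None,
    plan: tuple[ScreenDef, ...] = DEFAULT_PLAN,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a full multi-screen study with known ground truth.

    Returns the combined long-format well table (all screens of ``plan``)
    and the :class:`SimTruth` that generated it. Identical (config, spec,
    seed) inputs yield bit-identical tables.
    """
    if seed is None:
        seed = config.rng_seed
    truth = make_truth(config, spec, seed)
    layouts = _plate_layouts(config, truth.sirnas)

    sirna_tox = truth.sirnas.set_index("sirna_id")["toxic"]
    role_viability_loss = {
        "tox_ctrl": spec.tox_ctrl_viability_loss,
        "neg_ctrl": 0.0,
        "pos_ctrl_pathway": 0.0,
        "pos_ctrl_receptor": 0.0,
    }

    frames: list[pd.DataFrame] = []
    plate_records = []
    plate_counter = 0
    for screen in plan:
        n_rep = screen.replicates or config.replicates
        inhib = _sirna_inhibition(truth, spec, screen.stimulus)
        role_inhibition = {
            "neg_ctrl": 0.0,
            "pos_ctrl_pathway": spec.p65_effect,
            "pos_ctrl_receptor": spec.nod1_effect if screen.stimulus == "TriDAP" else 0.0,
            "tox_ctrl": 0.0,
        }
        # inhibition / toxicity vectors depend on layout and arm, not replicate
        layout_effects = []
        for layout in layouts:
            e = np.empty(len(layout))
            loss = np.empty(len(layout))
            for i, (sid, role) in enumerate(zip(layout["sirna_id"], layout["role"])):
                if role == "sample":
                    e[i] = inhib[sid]
                    loss[i] = spec.toxic_viability_loss if sirna_tox[sid] else 0.0
                else:
                    e[i] = role_inhibition[role]
                    loss[i] = role_viability_loss[role]
            layout_effects.append((e, loss))

        for rep in range(1, n_rep + 1):
            for p_idx, (layout, (e, loss)) in enumerate(
                zip(layouts, layout_effects), start=1
            ):
                rng = np.random.default_rng([seed, STREAM_PLATE0 + plate_counter])
                plate_counter += 1
                plate_id = f"{screen.screen_id}-r{rep}-p{p_idx:02d}"
                m = len(layout)
                plate_factor = float(_mean_one_lognormal(rng, spec.plate_effect_sd, 1)[0])

                t = _mean_one_lognormal(rng, spec.transfection_cv, m)
                v = t * (1.0 - loss)
                readout_viab = plate_factor * v * _mean_one_lognormal(
                    rng, spec.noise_cv_viability, m
                )
                a = spec.baseline_activity * (1.0 - e)
                readout_act = plate_factor * t * a * _mean_one_lognormal(
                    rng, spec.noise_cv_activity, m
                )

                frames.append(
                    pd.DataFrame(
                        {
                            "screen_id": screen.screen_id,
                            "plate_id": plate_id,
                            "well": layout["well"].to_numpy(),
                            "replicate": rep,
                            "sirna_id": layout["sirna_id"].to_numpy(),
                            "gene_id": layout["gene_id"].to_numpy(),
                            "role": layout["role"].to_numpy(),
                            "stimulus": screen.stimulus,
                            "readout_activity": readout_act,
                            "readout_viability": readout_viab,
                        }
                    )
                )
                plate_records.append({"plate_id": plate_id, "plate_factor": plate_factor})

    wells = pd.concat(frames, ignore_index=True)[WELL_COLUMNS]
    truth.plates = pd.DataFrame(plate_records)
    return wells, truth


# --------------------------------------------------------------------------
# Plate artifacts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateArtifact:
    """A gross plate failure to inject.

    kind ``transfection_failure`` scales the whole plate's viability readout
    by ``factor`` (global transfection failure -> plate mean drops below the
    QC floor); kind ``control_drift`` multiplies the plate's non-targeting
    control viabilities by mean-1 lognormal noise of CV ``factor``
    (inflating the control CV past the QC ceiling).
    """

    plate_id: str
    kind: str  # transfection_failure | control_drift
    factor: float


def inject_plate_artifacts(
    wells: pd.DataFrame, artifacts: list[PlateArtifact], seed: int = 0
) -> pd.DataFrame:
    """Return a modified copy of the well table; untouched plates identical."""
    out = wells.copy()
    known = set(out["plate_id"])
    for i, art in enumerate(artifacts):
        if art.plate_id not in known:
            raise ValueError(f"unknown plate id {art.plate_id!r}")
        on_plate = out["plate_id"] == art.plate_id
        if art.kind == "transfection_failure":
            out.loc[on_plate, "readout_viability"] *= art.factor
        elif art.kind == "control_drift":
            neg = on_plate & (out["role"] == "neg_ctrl")
            rng = np.random.default_rng([seed, 7000 + i])
            out.loc[neg, "readout_viability"] *= _mean_one_lognormal(
                rng, art.factor, int(neg.sum())
            )
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")
    return out


# --------------------------------------------------------------------------
# Recovery scoring
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """How well a ranking / hit set recovers the planted truth."""

    n_planted: int
    n_hits: int
    sensitivity: float
    fdp: float
    rank_recovery: float
    missed_by_cause: dict[str, int]
    false_by_cause: dict[str, int]


def evaluate_recovery(
    result: "pd.DataFrame | set[str]",
    truth: SimTruth,
    top_n: int,
) -> RecoveryReport:
    """Score recovery of the planted inhibitors.

    ``result`` is either a ranked gene table (from
    :func:`rnaiscreen.rsa.rank_genes`; the hit set is then its top ``top_n``
    genes) or an explicit hit gene set (e.g.
    ``TriageResult.final_shortlist``). ``rank_recovery`` is the fraction of
    planted inhibitors inside the top ``top_n`` of the ranking (equal to
    sensitivity when a set is passed). Errors are partitioned by planted
    cause: a missed inhibitor with a toxic siRNA counts as ``toxic``, a
    false positive carrying an off-target siRNA as ``off_target``,
    everything else as ``noise``.
    """
    planted = truth.inhibitors
    if isinstance(result, pd.DataFrame):
        ordered = list(result["gene_id"])
        hits = set(ordered[:top_n])
        in_top = planted & set(ordered[:top_n])
        rank_recovery = len(in_top) / len(planted) if planted else 1.0
    else:
        hits = set(result)
        rank_recovery = len(hits & planted) / len(planted) if planted else 1.0

    tp = hits & planted
    sensitivity = len(tp) / len(planted) if planted else 1.0
    fdp = len(hits - planted) / len(hits) if hits else 0.0

    by_gene_toxic = truth.sirnas.groupby("gene_id")["toxic"].any()
    by_gene_offt = (
        truth.sirnas.assign(ot=truth.sirnas["off_target_effect"] > 0)
        .groupby("gene_id")["ot"]
        .any()
    )
    missed: dict[str, int] = {"toxic": 0, "off_target": 0, "noise": 0}
    for g in planted - hits:
        if by_gene_toxic.get(g, False):
            missed["toxic"] += 1
        elif by_gene_offt.get(g, False):
            missed["off_target"] += 1
        else:
            missed["noise"] += 1
    false: dict[str, int] = {"toxic": 0, "off_target": 0, "noise": 0}
    for g in hits - planted:
        if by_gene_offt.get(g, False):
            false["off_target"] += 1
        elif by_gene_toxic.get(g, False):
            false["toxic"] += 1
        else:
            false["noise"] += 1
    return RecoveryReport(
        n_planted=len(planted),
        n_hits=len(hits),
        sensitivity=sensitivity,
        fdp=fdp,
        rank_recovery=rank_recovery,
        missed_by_cause=missed,
        false_by_cause=false,
    )


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------


def desk_preset() -> tuple[ScreenConfig, SimTruthSpec]:
    """Desk-scale study: 500 genes x 4 siRNAs in quadruplicate (~6 plates/arm)."""
    return ScreenConfig(), SimTruthSpec()


def fullscale_preset() -> tuple[ScreenConfig, SimTruthSpec]:
    """Library-scale study: ~7000 genes x 4 siRNAs in quadruplicate."""
    return ScreenConfig(), SimTruthSpec(
        n_genes=7000, n_inhibitors=350, n_decoy_offtarget_genes=140
    )
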
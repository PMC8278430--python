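"""Synthetic qRT-PCR case-control cohorts.

Generates well-level threshold-cycle (Ct) tables with the structure of a
serum-miRNA biomarker study: each subject contributes duplicate wells for
every marker assay plus an exogenous spike-in reference assay (cel-miR-39
style) used for normalization.  The generative model is normal on the Ct
(cycle) scale — i.e. log-normal on template abundance, the standard qPCR
noise assumption:

* per subject, a spike-in Ct is drawn once (one RNA extraction per sample),
  so spike-in variability is shared by all assays of that sample and cancels
  in dCt up to technical replicate noise;
* per subject and marker, a "true" dCt is drawn from a normal whose mean is
  ``control_mean_dct`` (controls) or ``control_mean_dct + effect_ddct``
  (cases) and whose SD is the between-subject ``subject_sd``;
* each well adds independent normal technical noise (``replicate_sd``);
* with probability ``outlier_prob`` a subject's dCt is shifted by
  ``outlier_shift`` (heavy-tailed individuals);
* with probability ``qc_fail_prob`` a duplicate pair is planted as
  discordant: replicate 2 is rewritten to replicate 1 ± ``qc_fail_shift``,
  guaranteeing the pair trips a duplicate-QC rule with threshold up to that
  shift;
* Ct values beyond ``max_cycles`` are emitted as missing, mirroring
  "undetermined" instrument output.

All randomness flows from the explicit ``seed``; identical specs produce
byte-identical tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import InputError

GROUP_CASE = "case"
GROUP_CONTROL = "control"
CT_COLUMNS = ["sample_id", "group", "assay", "replicate", "ct"]

DEFAULT_SPIKEIN_ASSAY = "cel-miR-39"


class MarkerSpec(BaseModel):
    """One marker assay of the simulated panel.

    ``effect_ddct`` is the group contrast of mean dCt (case − control) in
    cycles; negative values mean the marker is upregulated in cases (fewer
    cycles to threshold ⇒ more template).
    """

    name: str
    control_mean_dct: float
    effect_ddct: float = 0.0
    subject_sd: float = Field(gt=0)
    outlier_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    outlier_shift: float = 0.0


class CohortSpec(BaseModel):
    """Design of one simulated case-control qPCR cohort."""

    n_case: int = Field(ge=1)
    n_control: int = Field(ge=1)
    markers: list[MarkerSpec] = Field(min_length=1)
    spikein_assay: str = DEFAULT_SPIKEIN_ASSAY
    spikein_mean_ct: float = 21.0
    spikein_sd: float = Field(default=0.5, ge=0.0)
    replicate_sd: float = Field(default=0.05, ge=0.0)
    qc_fail_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    qc_fail_shift: float = Field(default=0.5, gt=0.0)
    max_cycles: float = Field(default=40.0, gt=0.0)
    seed: int

    @model_validator(mode="after")
    def _check_assay_names(self) -> "CohortSpec":
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("markers: assay names must be unique")
        if self.spikein_assay in names:
            raise ValueError(
                f"spikein_assay: {self.spikein_assay!r} collides with a marker name"
            )
        return self


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format Ct table for one cohort.

    Returns a DataFrame with columns ``sample_id, group, assay, replicate,
    ct``; exactly two rows (replicates 1 and 2) per sample × assay, with the
    spike-in assay first.  Missing Ct (beyond the detection limit) is NaN.
    """
    rng = np.random.default_rng(spec.seed)
    groups = [GROUP_CASE] * spec.n_case + [GROUP_CONTROL] * spec.n_control
    width = max(2, len(str(max(spec.n_case, spec.n_control))))
    sample_ids = [f"case_{i + 1:0{width}d}" for i in range(spec.n_case)] + [
        f"ctrl_{i + 1:0{width}d}" for i in range(spec.n_control)
    ]

    rows: list[tuple] = []
    for sample_id, group in zip(sample_ids, groups):
        spike_true = rng.normal(spec.spikein_mean_ct, spec.spikein_sd)
        assay_cts: list[tuple[str, float, float]] = []

        wells = spike_true + rng.normal(0.0, spec.replicate_sd, size=2)
        assay_cts.append((spec.spikein_assay, wells[0], wells[1]))

        for marker in spec.markers:
            mean_dct = marker.control_mean_dct
            if group == GROUP_CASE:
                mean_dct += marker.effect_ddct
            true_dct = rng.normal(mean_dct, marker.subject_sd)
            if marker.outlier_prob > 0 and rng.random() < marker.outlier_prob:
                true_dct += marker.outlier_shift
            wells = spike_true + true_dct + rng.normal(0.0, spec.replicate_sd, size=2)
            assay_cts.append((marker.name, wells[0], wells[1]))

        for assay, ct1, ct2 in assay_cts:
            if spec.qc_fail_prob > 0 and rng.random() < spec.qc_fail_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                ct2 = ct1 + sign * spec.qc_fail_shift
            for replicate, ct in ((1, ct1), (2, ct2)):
                rows.append(
                    (
                        sample_id,
                        group,
                        assay,
                        replicate,
                        np.nan if ct > spec.max_cycles else ct,
                    )
                )

    return pd.DataFrame(rows, columns=CT_COLUMNS)


def write_ct_table(records: pd.DataFrame, path) -> None:
    """Write a Ct table as CSV (default) or TSV (``.tsv`` extension).

    Missing Ct is written as an empty field.  Floats use shortest
    round-trip formatting, so ``read_ct_table`` recovers the values exactly.
    """
    if len(records) == 0:
        raise InputError("refusing to write an empty Ct table")
    sep = "\t" if str(path).endswith(".tsv") else ","
    records.to_csv(path, sep=sep, index=False, na_rep="")


def example_study_spec(seed: int = 0) -> CohortSpec:
    """A cohort spec emulating a four-marker serum-miRNA validation study.

    38 cases vs 28 controls, duplicate wells, a cel-miR-39 spike-in, and
    four markers whose group dCt shifts span ±1.6–2.8 cycles in both
    directions.  Between-subject SDs are set per marker so that the
    single-marker binormal discriminability Φ(|ddCt|/(σ·√2)) matches the
    kind of per-marker diagnostic accuracy (AUC ≈ 0.65–0.83) such panels
    report; see docs/methods.md.  The technical replicate SD of 0.05 cycles
    (typical duplicate-well precision) makes natural violations of the
    inclusive 0.2-cycle duplicate rule rare (~0.5% of pairs), matching the
    handful of QC exclusions such a study design implies.
    """
    markers = [
        MarkerSpec(name="miR-197-5p", control_mean_dct=6.0, effect_ddct=-2.83, subject_sd=2.14),
        MarkerSpec(name="miR-500a-5p", control_mean_dct=5.0, effect_ddct=+1.63, subject_sd=1.39),
        MarkerSpec(name="miR-424-5p", control_mean_dct=7.0, effect_ddct=-2.16, subject_sd=2.20),
        MarkerSpec(name="miR-664a-3p", control_mean_dct=6.5, effect_ddct=-2.83, subject_sd=5.20),
    ]
    return CohortSpec(n_case=38, n_control=28, markers=markers, seed=seed)


def subject_delta_ct(spec: CohortSpec) -> pd.DataFrame:
    """Convenience: per-subject *observed* dCt obtained by running the
    generated wells through mean-collapse and spike-in subtraction without
    QC (used for closed-form checks); columns sample_id, group, marker,
    delta_ct."""
    df = generate_cohort(spec)
    means = (
        df.groupby(["sample_id", "group", "assay"], sort=False)["ct"].mean().reset_index()
    )
    spike = means[means["assay"] == spec.spikein_assay].set_index("sample_id")["ct"]
    markers = means[means["assay"] != spec.spikein_assay].copy()
    markers["delta_ct"] = markers["ct"].to_numpy() - spike.loc[markers["sample_id"]].to_numpy()
    return markers.rename(columns={"assay": "marker"})[
        ["sample_id", "group", "marker", "delta_ct"]
    ]
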
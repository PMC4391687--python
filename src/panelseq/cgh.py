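"""Microarray CGH log2-ratio normalization and region-level dosage calling.

Two-channel probe intensities (sample vs reference DNA) are reduced to
log2 ratios and passed through a four-stage normalization stack:

1. sample dosage      — subtract the array-wide median log2 ratio;
2. LOWESS             — subtract a locally weighted fit of the ratio
                        against the reference-channel log intensity
                        (intensity-dependent dye/hybridization bias);
3. historic probe     — subtract each probe's median ratio over a panel of
                        prior wild-type arrays (probe affinity artifacts);
4. GC                 — subtract a LOWESS trend of the ratio against probe
                        GC fraction.

Every stage's adjustment is recorded so that raw - normalized equals the
sum of stage adjustments exactly.  On the normalized log2 scale wild type
sits at 0, a heterozygous deletion at log2(1/2) = -1 and a heterozygous
duplication at log2(3/2) = +0.585.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import PanelDefinition

DEL_THRESHOLD = -0.5
DUP_THRESHOLD = 0.4
MIN_PROBES = 3
LOWESS_FRAC = 0.3
MIN_HISTORIC_ARRAYS = 10

STAGE_COLUMNS = ["stage_sample", "stage_lowess", "stage_historic", "stage_gc"]


@dataclass(frozen=True)
class CGHCall:
    sample_id: str
    gene_name: str
    contig: str
    region_labels: tuple[str, ...]
    type: str  # "deletion" | "duplication"
    mean_log2: float
    n_probes: int


class HistoricProbeStats:
    """Per-probe median and SD of log2 ratios over prior wild-type arrays."""

    def __init__(self, median: pd.Series, sd: pd.Series, n_arrays: int,
                 min_arrays: int = MIN_HISTORIC_ARRAYS):
        if n_arrays < min_arrays:
            raise ValueError(
                f"historic stats need >= {min_arrays} arrays, got {n_arrays}"
            )
        self.median = median
        self.sd = sd
        self.n_arrays = n_arrays

    @classmethod
    def from_arrays(cls, arrays: list[pd.DataFrame],
                    min_arrays: int = MIN_HISTORIC_ARRAYS) -> "HistoricProbeStats":
        """Build historic stats from wild-type probe tables.

        Each array is taken through stages 1-2 only (the per-probe stages
        must not be trained on themselves), then per-probe medians/SDs are
        taken across arrays.
        """
        ratios = []
        for df in arrays:
            r = compute_log_ratios(df)
            n = normalize_cgh(r, historic=None, use_gc=False)
            ratios.append(n.set_index("probe_id")["normalized_log2"])
        mat = pd.concat(ratios, axis=1)
        return cls(median=mat.median(axis=1), sd=mat.std(axis=1, ddof=1),
                   n_arrays=len(arrays), min_arrays=min_arrays)


def compute_log_ratios(probes: pd.DataFrame) -> pd.DataFrame:
    """Add ``raw_log2`` = log2(sample_signal / reference_signal).

    Probes with a non-positive signal in either channel are masked
    (dropped, counted in ``attrs['masked_probes']``).
    """
    ok = (probes["sample_signal"] > 0) & (probes["reference_signal"] > 0)
    out = probes.loc[ok].copy()
    out["raw_log2"] = np.log2(out["sample_signal"] / out["reference_signal"])
    out.attrs["masked_probes"] = int((~ok).sum())
    return out


def normalize_cgh(
    probes: pd.DataFrame,
    historic: HistoricProbeStats | None = None,
    use_sample: bool = True,
    use_lowess: bool = True,
    use_gc: bool = True,
    lowess_frac: float = LOWESS_FRAC,
) -> pd.DataFrame:
    """Apply the four normalization stages in order; record each adjustment.

    Any stage can be disabled; a disabled stage contributes an adjustment
    of exactly 0.  Probes without historic statistics get a stage-3
    adjustment of 0 and are flagged in the ``historic_missing`` column.
    """
    out = probes.copy()
    if "raw_log2" not in out.columns:
        out = compute_log_ratios(out)
    ratio = out["raw_log2"].to_numpy(dtype=float).copy()

    # stage 1: sample dosage (array-wide median)
    s1 = np.full(len(out), np.median(ratio) if use_sample and len(out) else 0.0)
    if not use_sample:
        s1[:] = 0.0
    ratio -= s1

    # stage 2: LOWESS vs reference-channel log intensity.  The reference
    # channel is copy-number independent, so a genuine dosage change cannot
    # shift a probe along the x-axis and be smoothed away (an MA-style mean
    # intensity would absorb part of real deletions/duplications).
    s2 = np.zeros(len(out))
    if use_lowess and len(out) >= 10:
        a = np.log2(out["reference_signal"].to_numpy(dtype=float))
        s2 = lowess(ratio, a, frac=lowess_frac, return_sorted=False)
        s2 = np.nan_to_num(s2, nan=0.0)
    ratio -= s2

    # stage 3: historic probe median
    s3 = np.zeros(len(out))
    missing = np.zeros(len(out), dtype=bool)
    if historic is not None:
        med = historic.median.reindex(out["probe_id"])
        missing = med.isna().to_numpy()
        s3 = med.fillna(0.0).to_numpy(dtype=float)
    ratio -= s3

    # stage 4: GC trend
    s4 = np.zeros(len(out))
    if use_gc and len(out) >= 10:
        gc = out["gc_fraction"].to_numpy(dtype=float)
        s4 = lowess(ratio, gc, frac=lowess_frac, return_sorted=False)
        s4 = np.nan_to_num(s4, nan=0.0)
    ratio -= s4

    out["stage_sample"] = s1
    out["stage_lowess"] = s2
    out["stage_historic"] = s3
    out["stage_gc"] = s4
    out["historic_missing"] = missing
    out["normalized_log2"] = ratio
    return out


def call_cgh_regions(
    normalized: pd.DataFrame,
    panel: PanelDefinition,
    del_threshold: float = DEL_THRESHOLD,
    dup_threshold: float = DUP_THRESHOLD,
    min_probes: int = MIN_PROBES,
) -> list[CGHCall]:
    """Call region-level deletions/duplications from normalized log2 ratios.

    A region is aberrant when its mean normalized ratio crosses a threshold
    with at least ``min_probes`` probes individually beyond that threshold;
    adjacent aberrant regions of the same type merge into one event.
    Regions with fewer than ``min_probes`` probes are untestable.
    """
    calls: list[CGHCall] = []
    sample_ids = (normalized["sample_id"].unique()
                  if "sample_id" in normalized.columns else [""])
    for sample_id in sample_ids:
        df = (normalized[normalized["sample_id"] == sample_id]
              if "sample_id" in normalized.columns else normalized)
        by_region = df.groupby(["gene_name", "region_label"])["normalized_log2"]
        means = by_region.mean()
        counts = by_region.count()
        run: list[tuple] = []
        run_type: str | None = None

        def flush() -> None:
            nonlocal run, run_type
            if run and run_type:
                vals = [m for _, m, _ in run]
                calls.append(CGHCall(
                    sample_id=str(sample_id),
                    gene_name=run[0][0].gene_name,
                    contig=run[0][0].contig,
                    region_labels=tuple(r.region_label for r, _, _ in run),
                    type=run_type,
                    mean_log2=float(np.mean(vals)),
                    n_probes=sum(n for _, _, n in run),
                ))
            run, run_type = [], None

        prev_contig = None
        for contig in panel.contigs:
            for region in panel.regions_on(contig):
                key = (region.gene_name, region.region_label)
                if key not in means.index or counts[key] < min_probes:
                    flush()
                    continue
                if region.contig != prev_contig:
                    flush()
                prev_contig = region.contig
                m = means[key]
                sub = df[(df["gene_name"] == key[0]) & (df["region_label"] == key[1])]
                this = None
                if m < del_threshold:
                    if (sub["normalized_log2"] < del_threshold).sum() >= min_probes:
                        this = "deletion"
                elif m > dup_threshold:
                    if (sub["normalized_log2"] > dup_threshold).sum() >= min_probes:
                        this = "duplication"
                if this != run_type:
                    flush()
                if this:
                    run_type = this
                    run.append((region, float(m), int(counts[key])))
            flush()
    return calls


def calls_table(calls: list[CGHCall]) -> pd.DataFrame:
    cols = ["sample_id", "gene_name", "contig", "regions", "type",
            "mean_log2", "n_probes"]
    return pd.DataFrame([
        {"sample_id": c.sample_id, "gene_name": c.gene_name, "contig": c.contig,
         "regions": ";".join(c.region_labels), "type": c.type,
         "mean_log2": c.mean_log2, "n_probes": c.n_probes}
        for c in calls
    ], columns=cols)
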
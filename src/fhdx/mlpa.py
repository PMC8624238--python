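"""MLPA exon-dosage analysis.

Multiplex ligation-dependent probe amplification quantifies the copy
number of each targeted exon relative to reference probes and control
samples.  The dosage quotient (DQ) of a target probe is obtained by two
normalizations:

* intra-sample: each probe peak is divided by the mean of the reference
  probe peaks of the same sample, cancelling per-sample scale (DNA input,
  PCR efficiency, injection);
* inter-sample: the intra-sample ratio is divided by the median of the
  same ratio across control samples, so two-copy probes sit at DQ ~ 1.

A heterozygous deletion halves a probe's ligatable template and shows as
DQ ~ 0.5; a heterozygous duplication as DQ ~ 1.5.  Calls use standard
thresholds (deletion < 0.7, duplication > 1.3, homozygous deletion
< 0.25), and adjacent affected probes merge into one contiguous event,
named in HGVS "c.(x+1_y-1)_(z+1_w-1)del" style from exon cDNA
boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import MlpaConfig

PROMOTER = "promoter"
Target = Union[int, str]  # exon index or "promoter"


class SampleRole(str, enum.Enum):
    test = "test"
    control = "control"


@dataclass
class Probe:
    probe_id: str
    target: Optional[Target]  # None for reference probes
    is_reference: bool = False


@dataclass
class MlpaRun:
    """Peak-intensity matrix (samples x probes, arbitrary fluorescence
    units) with sample roles and probe metadata."""

    sample_roles: dict[str, SampleRole]
    probes: list[Probe]
    peaks: pd.DataFrame  # index: sample_id, columns: probe_id

    def __post_init__(self) -> None:
        ref = [p for p in self.probes if p.is_reference]
        if len(ref) < 2:
            raise ValueError("an MLPA run needs at least two reference probes")
        if not any(r == SampleRole.control for r in self.sample_roles.values()):
            raise ValueError("an MLPA run needs at least one control sample")
        if set(self.peaks.index) != set(self.sample_roles):
            raise ValueError("peak matrix rows must match the sample list")
        if set(self.peaks.columns) != {p.probe_id for p in self.probes}:
            raise ValueError("peak matrix columns must match the probe list")
        vals = self.peaks.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("peak intensities must be finite and non-negative")

    @property
    def reference_probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.is_reference]

    @property
    def target_probes(self) -> list[Probe]:
        return [p for p in self.probes if not p.is_reference]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, r in self.sample_roles.items() if r == SampleRole.control]

    @property
    def test_samples(self) -> list[str]:
        return [s for s, r in self.sample_roles.items() if r == SampleRole.test]


class EventType(str, enum.Enum):
    deletion = "deletion"
    duplication = "duplication"


@dataclass
class DosageCall:
    sample_id: str
    event: EventType
    targets: list[Target]  # contiguous in probe order
    mean_dq: float
    probe_dq: dict[str, float] = field(default_factory=dict)
    homozygous: bool = False
    hgvs: Optional[str] = None

    @property
    def exon_span(self) -> Optional[tuple[int, int]]:
        """Inclusive (first, last) exon range, or None for promoter-only."""
        exons = [t for t in self.targets if isinstance(t, int)]
        return (min(exons), max(exons)) if exons else None


def normalize_run(run: MlpaRun, config: Optional[MlpaConfig] = None) -> pd.DataFrame:
    """Dosage-quotient table (all samples x target probes).

    By construction the median DQ of every probe across control samples
    is exactly 1.
    """
    ref_ids = run.reference_probe_ids
    ref_means = run.peaks[ref_ids].mean(axis=1)
    zero = ref_means[ref_means == 0]
    if len(zero):
        raise ValueError(f"all reference peaks are zero in sample {zero.index[0]!r}")

    target_ids = [p.probe_id for p in run.target_probes]
    intra = run.peaks[target_ids].div(ref_means, axis=0)

    control_median = intra.loc[run.control_samples].median(axis=0)
    zero_probes = control_median[control_median == 0]
    if len(zero_probes):
        raise ValueError(f"zero control median for probe {zero_probes.index[0]!r}")
    return intra.div(control_median, axis=1)


def _probe_order(run_or_probes, exon_order: Sequence[Target]) -> list[Probe]:
    probes = run_or_probes.target_probes if isinstance(run_or_probes, MlpaRun) else run_or_probes
    rank = {t: i for i, t in enumerate(exon_order)}
    for p in probes:
        if p.target not in rank:
            raise ValueError(f"exon_order is missing target {p.target!r} (probe {p.probe_id})")
    return sorted(probes, key=lambda p: rank[p.target])


def call_exon_events(
    dq: pd.DataFrame,
    probes: Sequence[Probe],
    exon_order: Sequence[Target],
    config: Optional[MlpaConfig] = None,
    samples: Optional[Sequence[str]] = None,
) -> list[DosageCall]:
    """Per-sample CNV calls: threshold each probe's DQ, then merge adjacent
    probes (in exon order) sharing the same aberrant state."""
    cfg = config or MlpaConfig()
    ordered = _probe_order(list(probes), exon_order)
    calls: list[DosageCall] = []
    for sample in samples if samples is not None else dq.index:
        states = []
        for p in ordered:
            v = float(dq.loc[sample, p.probe_id])
            if v < cfg.deletion_threshold:
                states.append(EventType.deletion)
            elif v > cfg.duplication_threshold:
                states.append(EventType.duplication)
            else:
                states.append(None)
        i = 0
        while i < len(ordered):
            state = states[i]
            if state is None:
                i += 1
                continue
            j = i
            while j + 1 < len(ordered) and states[j + 1] == state:
                j += 1
            segment = ordered[i : j + 1]
            probe_dq = {p.probe_id: float(dq.loc[sample, p.probe_id]) for p in segment}
            mean_dq = float(np.mean(list(probe_dq.values())))
            calls.append(
                DosageCall(
                    sample_id=sample,
                    event=state,
                    targets=[p.target for p in segment],
                    mean_dq=mean_dq,
                    probe_dq=probe_dq,
                    homozygous=(
                        state == EventType.deletion
                        and mean_dq < cfg.homozygous_deletion_threshold
                    ),
                )
            )
            i = j + 1
    return calls


def format_deletion_hgvs(
    call: DosageCall,
    boundaries: dict[int, int],
    transcript: str = "NM_000527.4",
) -> str:
    """HGVS name for a whole-exon deletion with unknown intronic
    breakpoints: deleting exons a..b is written
    ``c.(x+1_y-1)_(z+1_w-1)del`` with x = cDNA end of exon a-1, y = x+1,
    z = cDNA end of exon b, w = z+1.
    """
    if call.event != EventType.deletion:
        raise ValueError("HGVS deletion naming applies to deletion calls only")
    span = call.exon_span
    if span is None:
        raise ValueError("promoter-only events have no exonic HGVS name")
    first, last = span
    for needed in (first - 1, last):
        if needed not in boundaries:
            raise ValueError(f"exon boundary table is missing exon {needed}")
    x = boundaries[first - 1]
    z = boundaries[last]
    return f"{transcript}:c.({x}+1_{x + 1}-1)_({z}+1_{z + 1}-1)del"


def calls_to_frame(calls: list[DosageCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        span = c.exon_span
        rows.append({
            "sample_id": c.sample_id,
            "event": c.event.value,
            "targets": ",".join(str(t) for t in c.targets),
            "exon_start": span[0] if span else "NA",
            "exon_end": span[1] if span else "NA",
            "mean_dq": round(c.mean_dq, 4),
            "homozygous": int(c.homozygous),
            "hgvs": c.hgvs or "NA",
        })
    return pd.DataFrame(
        rows,
        columns=["sample_id", "event", "targets", "exon_start", "exon_end",
                 "mean_dq", "homozygous", "hgvs"],
    )
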
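"""Call LDLR exon deletions from simulated MLPA runs.

Simulates a run with two heterozygous deletions (exons 2-10 in one
sample, exon 15 in another, copy ratio 0.5), normalizes probe peaks to
dosage quotients and calls contiguous events with HGVS names.
"""

from fhdx import call_exon_events, format_deletion_hgvs, normalize_run
from fhdx.io import load_ldlr_exon_boundaries
from fhdx.synth import gen_mlpa_run

run = gen_mlpa_run(
    n_samples=2,
    events=[("S001", (2, 10), 0.5), ("S002", (15, 15), 0.5)],
    noise_sd=0.02,
    seed=1,
)
dq = normalize_run(run)
order = [p.target for p in run.target_probes]
calls = call_exon_events(dq, run.target_probes, order, samples=run.test_samples)
boundaries = load_ldlr_exon_boundaries()
for c in calls:
    print(f"{c.sample_id}: {c.event.value} of exons "
          f"{c.exon_span[0]}-{c.exon_span[1]} (mean DQ {c.mean_dq:.2f})")
    print(f"  {format_deletion_hgvs(c, boundaries)}")
# A dosage quotient near 0.5 means one of two copies is missing
# (heterozygous deletion); ~1.0 means two normal copies.
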
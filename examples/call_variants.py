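"""Call pooled variants in one bulk under the five-filter stack.

Reads are filtered (pairing, mapping uniqueness, central quality >= 20,
neighbourhood quality >= 15), then alleles are accepted at count >= 4 and
frequency >= 20% with >= 20% of supporting reads on each strand, and the
frequency is snapped to the nearest tetraploid dosage.
"""

import tetrabsa as tb

study = tb.simulate_study(tb.SimConfig(seed=1, n_neutral_sites=20))
params = tb.CallerParams()
calls = tb.call_bulk(study.pileup_high, study.reference, params)

print(f"{len(calls)} sites called in the high bulk (of {len(study.truth)} simulated sites)")
for key in list(calls)[:5]:
    for c in calls[key]:
        print(
            f"{c.contig}:{c.position} {c.ref_allele}>{c.allele} "
            f"count={c.count}/{c.effective_coverage} freq={c.frequency:.2f} "
            f"dosage~{c.nearest_dosage:.2f} fwd={c.forward_fraction:.2f} q={c.mean_base_quality:.1f}"
        )
print(
    "Each call reports its read support, post-filter coverage, and the nearest "
    "tetraploid allele dosage (25/50/75/100%); alleles failing any filter "
    "clause are absent."
)
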
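"""Category proportion tables with two-proportion z-tests.

Simulates one arm whose canonical share shifts between two conditions
(44.29% -> 55.05%, a redistribution between the canonical form and its 3'
deletion isomiR), pools replicates within condition, and prints the
per-condition proportion block with the per-category z-test p-values.
"""

from isomirseq import IsomiRSpectrumConfig, SpectrumEntry, simulate_reads
from isomirseq.isomir import build_isomir_table
from isomirseq.pipeline import default_synthetic_references
from isomirseq.preprocess import align_sample, collapse_and_filter, trim_adapter
from isomirseq.quantify import add_proportion_ztests, proportion_table

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
hairpins, arms = default_synthetic_references(seed=0)

alignments = {}
conditions = {}
for cond, canon in (("SEN", 0.4429), ("SEN+M", 0.5505)):
    spectrum = {"syn-miR-1-5p": [SpectrumEntry(0, 0, "", canon),
                                 SpectrumEntry(0, -1, "", 1 - canon)]}
    cfg = IsomiRSpectrumConfig(spectrum, reads_per_sample=10000,
                               sequencing_error_rate=0.0, rng_seed=2)
    sample = f"{cond.replace('+', '')}_1"
    reads, _ = simulate_reads(cfg, hairpins, arms, samples=[sample])
    trimmed = [trim_adapter(seq, ADAPTER)[0] for seq, _ in reads[sample]]
    collapsed, _ = collapse_and_filter(trimmed)
    alignments[sample], _ = align_sample(collapsed, hairpins, arms)
    conditions[sample] = cond

records = build_isomir_table(alignments, hairpins, list(conditions))
table = proportion_table(records, conditions)
table = add_proportion_ztests(table)

cols = ["name", "condition", "total", "pct_canonical", "pct_3p_deletion",
        "pct_uridylation"]
print(table[cols].round(4).to_string(index=False))
print()
print("The two condition rows show the planted 44.29/55.71 and 55.05/44.95")
print("splits recovered exactly (deterministic largest-remainder allocation);")
print("the p(...) row is the pooled two-proportion z-test per category —")
print("well below 0.001 for a shift of this size at 10,000 reads.")
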
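"""Trim 3' adapters from simulated reads and collapse them into counted tags.

Builds a tiny simulated library, cleans it, and prints the tag table head.
"""

from sharkmir.reads_io import RawRead, clean_reads, collapse_libraries
from sharkmir.synthetic_fixtures import SimConfig, build_genome, simulate_reads

config = SimConfig(seed=1, n_hairpins=3, n_duplex=1, n_known=1, read_depth=20,
                   noise_reads=2)
sim = build_genome(config)
reads, truth_counts = simulate_reads(sim, library_id="LN")

inserts, stats = clean_reads(
    (RawRead(r, s, q) for r, s, q in reads), config.adapter
)
tags, libraries = collapse_libraries({"LN": inserts})

print(f"{stats.total_raw} raw reads -> {stats.clean} clean inserts "
      f"({stats.no_adapter} without adapter, {stats.junk} junk)")
print(f"{len(tags)} unique tags; library total = "
      f"{libraries[0].total_clean_reads} reads")
print("\ntop tags (sequence, count):")
for tag in tags[:5]:
    print(f"  {tag.sequence}  x{tag.counts['LN']}")
# Each line is one distinct 15-30 nt small RNA; the count is how many
# sequenced reads collapsed onto it, the unit of all later quantification.
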
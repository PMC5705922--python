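"""Generate a synthetic water-column fixture and look at what was planted.

The generator emulates a 7-depth x 12-occasion sampling design with
depth-stratified phage populations, a lysogeny gradient below the deep
chlorophyll maximum, and a short-contig tail carrying one cellular
contaminant. The planted truth is kept separate from the files a pipeline
would consume.
"""

from collections import Counter

from phagedepth.synthetic_data import SimConfig, generate_fixture

fixture = generate_fixture(SimConfig(seed=1))

print(f"samples: {len(fixture.samples)} "
      f"({fixture.samples['depth_m'].nunique()} depths x "
      f"{fixture.samples['date'].nunique()} occasions, one grid cell missing)")
print(f"contigs: {len(fixture.contigs)} "
      f"({fixture.config.n_contigs} candidates >= 20 kbp + "
      f"{fixture.config.n_short_contigs} shorter)")
print(f"genes on contigs: {len(fixture.genes)}")
print("planted distribution groups:", dict(Counter(fixture.truth.depth_group.values())))
print("planted mesopelagic:surface lysogeny fold:", fixture.truth.lysogeny["fold"])
print("contaminant contigs:", fixture.truth.contaminant_contig_ids)

# Each contig's per-sample coverage is run-length encoded per-base depth;
# the same seed always regenerates byte-identical files.
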
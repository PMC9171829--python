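"""File-based workflow: simulate, write standard formats, rebuild a library.

Writes a dataset as MGF + cluster TSV + PSM TSV, reads everything back
through the io layer, generates BIN consensus spectra and writes them as a
consensus MGF — the same path the `speccons` command line drives.
"""

import tempfile
from pathlib import Path

from speccons import (
    SimConfig,
    generate_consensus,
    make_dataset,
    read_clusters,
    read_mgf,
    read_psms,
    write_mgf,
)

workdir = Path(tempfile.mkdtemp())
make_dataset(
    SimConfig(n_clusters=4, members_per_cluster=3, seed=3), out_dir=workdir
)
print("wrote:", ", ".join(p.name for p in sorted(workdir.iterdir())))

spectra = {s.spectrum_id: s for s in read_mgf(workdir / "spectra.mgf")}
clusters = read_clusters(workdir / "clusters.tsv")
psms = read_psms(workdir / "psms.tsv")
print(f"read back {len(spectra)} spectra, {len(clusters)} clusters, {len(psms)} PSMs")

run = generate_consensus(clusters, spectra, "bin", psms=psms)
out = workdir / "consensus_bin.mgf"
write_mgf(run.records, out)
print(f"consensus: {run.n_records_out} records, {run.n_skipped} skipped -> {out.name}")
print("\nfirst consensus block:")
for line in out.read_text().splitlines()[:6]:
    print(" ", line)

# The TITLE line encodes the source cluster, the method and the cluster
# size, so downstream search results can be joined back to clusters.
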
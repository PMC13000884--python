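"""Run a scaled-down end-to-end pipeline: build a helix, fragment it,
generate synthetic tensors, transfer them to jittered snapshots,
average the spectra and analyze the mean.

The full-size demo ((PHG)9PHA triple helix, 10 snapshots) is what
`collagen-roa run` executes; here a single strand with 3 snapshots
keeps the example quick.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

from collagen_roa import RunConfig, run_pipeline

with TemporaryDirectory() as tmp:
    config = RunConfig(
        sequence="(PHG)3PHA",
        n_chains=1,
        window=4,
        n_snapshots=3,
        seed=1,
        out_dir=str(Path(tmp) / "demo"),
    )
    manifest = run_pipeline(config)
    print("stages:", " -> ".join(manifest["stages"]))
    print(f"artifacts written: {len(manifest['artifacts'])} "
          "(helix.pdb, fragments/, per-snapshot spectra, mean, report)")
    report = json.loads((Path(tmp) / "demo" / "report.json").read_text())
    print(f"mean spectrum: median |CID| = {report['cid_median_abs']:.2e}, "
          f"max |CID| = {report['cid_max_abs']:.2e}")
    print("-> circular intensity differences stay in the weak-chirality regime")
    print("   the synthetic tensors were calibrated to (~1e-3).")
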
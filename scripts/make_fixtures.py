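#!/usr/bin/env python
"""Regenerate the committed fixture bundles under src/densiwit/fixtures/data/.

Runs the in-package electronic-structure engine (RHF + active-space exact
diagonalization; full CI for the witness), writes Molden + 1-RDM JSON bundles,
and refreshes the SHA-256 manifest. Deterministic; takes a few minutes
(dominated by the aug-cc-pVTZ witness integrals).

Usage:  python scripts/make_fixtures.py [names...]
"""

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np

from densiwit.chem_io import write_molden, write_rdm_bundle
from densiwit.fixtures.catalog import FIXTURES, build_fixture

DATA = Path(__file__).resolve().parent.parent / "src/densiwit/fixtures/data"


def main(argv):
    names = argv[1:] or list(FIXTURES)
    DATA.mkdir(parents=True, exist_ok=True)
    manifest_path = DATA / "hashes.json"
    hashes = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    for name in names:
        t0 = time.time()
        wfn, rdm, info = build_fixture(name)
        molden = write_molden(wfn, title=wfn.label)
        bundle = write_rdm_bundle(rdm)
        for fname, text in ((f"{name}.molden", molden),
                            (f"{name}.rdm.json", bundle)):
            (DATA / fname).write_text(text)
            hashes[fname] = hashlib.sha256(text.encode()).hexdigest()
        print(f"{name}: E = {info['energy']:.8f} Eh  "
              f"active trace = {np.trace(rdm.matrix):.6f}  "
              f"({time.time() - t0:.1f} s)  {info}")
    manifest_path.write_text(json.dumps(hashes, indent=1) + "\n")
    print(f"wrote {manifest_path}")


if __name__ == "__main__":
    main(sys.argv)
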
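#!/usr/bin/env python
"""Download the deposited genome-scale model (BioModels MODEL2102080001).

Requires network access; run once, then the reproduction tests in
tests/test_acceptance.py and `fluxscan conditions models/MODEL2102080001.xml`
can use the file.
"""

import sys
import urllib.request
from pathlib import Path

URL = (
    "https://www.ebi.ac.uk/biomodels/model/download/MODEL2102080001"
    "?filename=MODEL2102080001_url.xml"
)
DEST = Path(__file__).resolve().parents[1] / "models" / "MODEL2102080001.xml"


def main() -> int:
    DEST.parent.mkdir(parents=True, exist_ok=True)
    print(f"downloading {URL}")
    try:
        with urllib.request.urlopen(URL, timeout=60) as resp:
            data = resp.read()
    except OSError as exc:
        print(f"download failed: {exc}", file=sys.stderr)
        return 1
    DEST.write_bytes(data)
    print(f"wrote {DEST} ({len(data)} bytes)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
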
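#!/usr/bin/env python
"""Download the two deposited coordinate files used by the accession-based
spot checks (tests/test_acceptance.py criteria 5-6) and by
scripts/acceptance.py, into data/.

Requires network access; the files are mmCIF text from the RCSB.

Usage:
    python scripts/fetch_data.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

DATA_DIR = Path(__file__).resolve().parent.parent / "data"
ACCESSIONS = ("6S2M", "6S2S")
URL = "https://files.rcsb.org/download/{}.cif"


def main() -> int:
    DATA_DIR.mkdir(exist_ok=True)
    status = 0
    for accession in ACCESSIONS:
        target = DATA_DIR / f"{accession.lower()}.cif"
        if target.exists():
            print(f"{target} already present", file=sys.stderr)
            continue
        url = URL.format(accession)
        try:
            with urllib.request.urlopen(url, timeout=60) as response:
                target.write_bytes(response.read())
            print(f"fetched {url} -> {target}", file=sys.stderr)
        except Exception as exc:
            print(f"failed to fetch {url}: {exc}", file=sys.stderr)
            status = 1
    return status


if __name__ == "__main__":
    sys.exit(main())
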
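#!/usr/bin/env python
"""Download the deposited hexapeptide crystal structures into
data/deposited/ so the validation tests against published values can
run. Requires network access; each entry is a ~100 KB PDB file.

Usage:
    python scripts/fetch_deposited.py
"""

from __future__ import annotations

import sys
import urllib.error
import urllib.request
from pathlib import Path

ENTRIES = ("8QWV", "8QWU", "8QWW", "8ANM", "8ANI", "8ANG")
MIRRORS = [
    "https://files.rcsb.org/download/{code}.pdb",
    "https://www.ebi.ac.uk/pdbe/entry-files/download/pdb{lower}.ent",
]
TARGET = Path(__file__).resolve().parent.parent / "data" / "deposited"


def fetch(code: str) -> bool:
    out = TARGET / f"{code}.pdb"
    if out.exists() and out.stat().st_size > 0:
        print(f"{code}: already present")
        return True
    for mirror in MIRRORS:
        url = mirror.format(code=code, lower=code.lower())
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                data = resp.read()
            if data:
                out.write_bytes(data)
                print(f"{code}: fetched {len(data)} bytes")
                return True
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            print(f"{code}: {url} failed ({exc})")
    return False


def main():
    TARGET.mkdir(parents=True, exist_ok=True)
    ok = all([fetch(code) for code in ENTRIES])
    sys.exit(0 if ok else 1)


if __name__ == "__main__":
    main()
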
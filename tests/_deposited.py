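"""Access to the deposited crystal structures used for validation.

The six entries are tiny hexapeptide crystals (~100 KB PDB files). They
are not redistributed with the package; they are looked up in
``data/deposited/`` (populated by ``scripts/fetch_deposited.py``) or
fetched on the fly when the network allows.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parent.parent
CACHE_DIRS = [REPO_ROOT / "data" / "deposited", REPO_ROOT / "scratch" / "deposited"]
MIRRORS = [
    "https://files.rcsb.org/download/{code}.pdb",
    "https://www.ebi.ac.uk/pdbe/entry-files/download/pdb{lower}.ent",
]

ENTRIES = ("8QWV", "8QWU", "8QWW", "8ANM", "8ANI", "8ANG")

_failed: set = set()  # per-session memo of unavailable entries


def deposited_path(code: str, timeout: float = 10.0) -> Path | None:
    """Local path of a deposited entry, downloading once if possible."""
    code = code.upper()
    if code in _failed:
        return None
    for d in CACHE_DIRS:
        p = d / f"{code}.pdb"
        if p.exists() and p.stat().st_size > 0:
            return p
    target_dir = CACHE_DIRS[-1]
    target_dir.mkdir(parents=True, exist_ok=True)
    target = target_dir / f"{code}.pdb"
    for mirror in MIRRORS:
        url = mirror.format(code=code, lower=code.lower())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
            if data:
                target.write_bytes(data)
                return target
        except (urllib.error.URLError, OSError, TimeoutError):
            continue
    _failed.add(code)
    return None


def require(code: str):
    """Path to a deposited entry or a test failure explaining why not."""
    import pytest

    p = deposited_path(code)
    if p is None:
        pytest.fail(
            f"deposited structure {code} unavailable: not cached under "
            "data/deposited/ and no network route to the PDB; run "
            "scripts/fetch_deposited.py on a networked machine first"
        )
    return p
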
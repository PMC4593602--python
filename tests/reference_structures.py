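"""Access to experimental reference structures for validation tests.

The validation targets are published crystal structures; they are too
large to ship as test data, so they are looked up in
``tests/data/reference_structures/<ID>.pdb`` first and, failing that,
fetched from the RCSB with a short timeout.  Tests using them fail with a
clear diagnostic when the structure is unavailable (e.g. offline and no
local copy) — the assertion they encode is against the real structure and
cannot be satisfied by a stand-in.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

DATA_DIR = Path(__file__).parent / "data" / "reference_structures"
_RCSB = "https://files.rcsb.org/download/{pdb_id}.pdb"
_TIMEOUT = 20.0  # seconds per attempt


def fetch_pdb(pdb_id: str) -> Path:
    """Path to <pdb_id>.pdb, from the local cache or a fresh download.

    Raises FileNotFoundError with a diagnostic when neither works.
    """
    pdb_id = pdb_id.upper()
    local = DATA_DIR / f"{pdb_id}.pdb"
    if local.exists() and local.stat().st_size > 0:
        return local
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    url = _RCSB.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=_TIMEOUT) as response:
            data = response.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FileNotFoundError(
            f"reference structure {pdb_id} unavailable: not in {DATA_DIR} "
            f"and download from {url} failed ({exc}). Place the PDB file "
            f"there to run this validation offline."
        ) from exc
    local.write_bytes(data)
    return local
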
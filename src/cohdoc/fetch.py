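"""Convenience download of deposited coordinate files (mmCIF) from wwPDB.

Strictly optional plumbing: every analysis runs on any local PDB/mmCIF
file, and the synthetic fixtures cover the test suite without downloads.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .errors import CohdocError

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


class FetchError(CohdocError):
    """The deposited entry could not be retrieved."""


def fetch_structure(
    pdb_id: str, dest_dir: str | Path = ".", timeout: float = 10.0
) -> Path:
    """Download ``<pdb_id>.cif`` into ``dest_dir`` (cached if already there)."""
    pdb_id = pdb_id.upper()
    dest = Path(dest_dir) / f"{pdb_id}.cif"
    if dest.exists():
        return dest
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(f"cannot retrieve {pdb_id} from {url}: {exc}") from exc
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    return dest
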
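"""Download coordinate files from the PDB by accession, with a local cache.

The entry mmCIF endpoint is used (mmCIF handles very large structures).
Cache directory resolution order: explicit argument, ``MOLRAY_CACHE``
environment variable, ``~/.cache/molray``.  Once cached, reruns are offline.
"""

from __future__ import annotations

import os
import re
import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb", "FetchNotFoundError", "FetchRetryableError"]

_URL_TEMPLATE = "https://files.rcsb.org/download/{accession}.cif"


class FetchNotFoundError(ValueError):
    """The accession does not exist at the PDB."""


class FetchRetryableError(RuntimeError):
    """Transient network failure; retrying later may succeed."""


def cache_dir(override: str | Path | None = None) -> Path:
    if override is not None:
        return Path(override)
    env = os.environ.get("MOLRAY_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "molray"


def fetch_pdb(
    accession: str,
    cache: str | Path | None = None,
    timeout: float = 60.0,
) -> str:
    """Return the entry mmCIF text for a 4-character PDB accession."""
    acc = accession.strip().lower()
    if not re.fullmatch(r"[0-9][a-z0-9]{3}", acc):
        raise ValueError(f"invalid PDB accession {accession!r}")
    cdir = cache_dir(cache)
    cached = cdir / f"{acc}.cif"
    if cached.exists():
        return cached.read_text()

    url = _URL_TEMPLATE.format(accession=acc)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise FetchNotFoundError(f"PDB entry {accession!r} not found") from exc
        raise FetchRetryableError(f"HTTP {exc.code} fetching {url}") from exc
    except (urllib.error.URLError, OSError) as exc:
        raise FetchRetryableError(f"network failure fetching {url}: {exc}") from exc

    cdir.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    return text
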
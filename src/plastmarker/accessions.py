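"""Loading of deposited genome records for accession-based checks.

Records are looked up as plain files under ``data/accessions/`` in the
repository (``<ACC>.gb`` or ``<ACC>.fasta``), an explicit directory, or the
``PLASTMARKER_ACCESSION_DIR`` environment variable.  ``fetch=True``
additionally tries an NCBI efetch download (short timeout) and caches the
result; offline environments simply get ``None``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional

from .plastome_io import Plastome, PlastomeError, read_plastome

logger = logging.getLogger("plastmarker")

_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)


def accession_dirs(explicit: Optional[str | Path] = None) -> list[Path]:
    dirs = []
    if explicit:
        dirs.append(Path(explicit))
    env = os.environ.get("PLASTMARKER_ACCESSION_DIR")
    if env:
        dirs.append(Path(env))
    here = Path(__file__).resolve()
    dirs.append(here.parents[2] / "data" / "accessions")  # repo checkout
    dirs.append(Path.cwd() / "data" / "accessions")
    return dirs


def load_accession(
    acc: str,
    directory: Optional[str | Path] = None,
    fetch: bool = False,
    timeout: float = 10.0,
) -> Optional[Plastome]:
    """Load a deposited record from disk (optionally fetching it first)."""
    for d in accession_dirs(directory):
        for suffix, fmt in ((".gb", "genbank_flat"), (".gbk", "genbank_flat"),
                            (".fasta", "fasta"), (".fa", "fasta")):
            path = d / f"{acc}{suffix}"
            if path.exists():
                try:
                    return read_plastome(path, format=fmt)
                except PlastomeError as exc:
                    logger.warning("could not parse %s: %s", path, exc)
    if fetch:
        text = _try_fetch(acc, timeout)
        if text:
            cache = accession_dirs(directory)[-2]
            try:
                cache.mkdir(parents=True, exist_ok=True)
                path = cache / f"{acc}.gb"
                path.write_text(text)
                return read_plastome(path, format="genbank_flat")
            except (OSError, PlastomeError) as exc:
                logger.warning("fetched %s but could not use it: %s", acc, exc)
    return None


def _try_fetch(acc: str, timeout: float) -> Optional[str]:
    import urllib.error
    import urllib.request

    try:
        with urllib.request.urlopen(_EFETCH.format(acc=acc), timeout=timeout) as fh:
            text = fh.read().decode()
        if text.startswith("LOCUS"):
            return text
    except (urllib.error.URLError, OSError, TimeoutError):
        pass
    logger.info("accession %s not downloadable in this environment", acc)
    return None
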
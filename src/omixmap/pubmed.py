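"""Optional PubMed co-mention counter (network adapter).

Counts publications whose title or abstract mentions both a disease term and
a gene symbol, through the NCBI E-utilities esearch endpoint.  Results are
cached on disk together with the exact query string for auditability, the
client sleeps between requests to respect the rate limit, and failures are
recorded as missing entries — never as fabricated zero counts.  The rest of
the evaluation machinery consumes plain count tables, so this module is never
touched by offline analyses or the test suite's default path.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Optional, Sequence

from .config import get_logger

__all__ = ["fetch_pubmed_counts", "OfflineError"]

logger = get_logger(__name__)

ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
MIN_INTERVAL_S = 0.34
RETRIES = 3


class OfflineError(RuntimeError):
    """Raised when a network fetch is requested in offline mode."""


def _query(disease: str, gene: str) -> str:
    return f"({disease}[Title/Abstract]) AND ({gene}[Title/Abstract])"


def _esearch_count(term: str, timeout: float) -> int:
    url = ESEARCH + "?" + urllib.parse.urlencode(
        {"db": "pubmed", "term": term, "retmode": "json", "rettype": "count"})
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = json.loads(resp.read().decode())
    return int(data["esearchresult"]["count"])


def fetch_pubmed_counts(disease_term: str, genes: Sequence[str],
                        cache_path: Optional[str | Path] = None,
                        offline: bool = False,
                        timeout: float = 10.0) -> dict[str, int]:
    """Publication counts for disease-gene co-mentions in title/abstract.

    Returns a dict with an entry per gene that could be resolved; failed
    lookups are simply absent.  ``offline=True`` refuses any network call
    (cache hits are still served).
    """
    cache: dict[str, dict] = {}
    cache_file = Path(cache_path) if cache_path else None
    if cache_file and cache_file.exists():
        cache = json.loads(cache_file.read_text())
    out: dict[str, int] = {}
    dirty = False
    last_call = 0.0
    for gene in genes:
        term = _query(disease_term, gene)
        if term in cache:
            logger.info("fetch_pubmed_counts: cache hit for %s", gene)
            out[gene] = int(cache[term]["count"])
            continue
        if offline:
            raise OfflineError(
                f"offline mode: no cached count for {disease_term!r} / "
                f"{gene!r}; refusing a partial result")
        count = None
        for attempt in range(RETRIES):
            wait = MIN_INTERVAL_S - (time.monotonic() - last_call)
            if wait > 0:
                time.sleep(wait)
            last_call = time.monotonic()
            try:
                count = _esearch_count(term, timeout)
                break
            except (urllib.error.URLError, KeyError, ValueError) as exc:
                logger.warning("fetch_pubmed_counts: attempt %d for %s "
                               "failed: %s", attempt + 1, gene, exc)
        if count is None:
            logger.warning("fetch_pubmed_counts: %s marked missing", gene)
            continue
        out[gene] = count
        cache[term] = {"count": count, "query": term}
        dirty = True
    if cache_file and dirty:
        cache_file.write_text(json.dumps(cache, indent=1, sort_keys=True))
    return out
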
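"""Live PubMed backend over NCBI eUtils (ePost/eSearch/eFetch with history).

Requires network access; the test suite and the offline pipeline use
:class:`litcurate.fixtures.FixtureBackend` instead.
"""

from __future__ import annotations

import time
from typing import Optional, Sequence

from .article_store import ArticleRecord, parse_medline_xml
from .query_engine import BackendError, BooleanQuery, SearchOutcome, render_query


class EntrezBackend:
    """PubMed search/fetch via Biopython's Entrez client.

    ``email`` is required by NCBI's usage policy; ``api_key`` raises the
    rate limit.  Queries render in the pubmed dialect, so the question's
    clinical-queries filter is applied server-side.
    """

    def __init__(
        self,
        email: str,
        api_key: Optional[str] = None,
        retmax: int = 200,
        delay: float = 0.34,
    ):
        from Bio import Entrez  # deferred: offline installs never touch it

        self._entrez = Entrez
        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self.retmax = retmax
        self.delay = delay
        self._history: Optional[tuple[str, str]] = None  # (WebEnv, QueryKey)

    def search(self, query: BooleanQuery) -> SearchOutcome:
        rendered = render_query(query, dialect="pubmed")
        try:
            time.sleep(self.delay)
            with self._entrez.esearch(
                db="pubmed", term=rendered, retmax=self.retmax, usehistory="y"
            ) as handle:
                result = self._entrez.read(handle)
        except Exception as exc:
            raise BackendError(f"eSearch failed: {exc}", query) from exc
        self._history = (result["WebEnv"], result["QueryKey"])
        return SearchOutcome(tuple(result["IdList"]), int(result["Count"]))

    def fetch(self, ids: Sequence[str]) -> list[ArticleRecord]:
        try:
            time.sleep(self.delay)
            kwargs = dict(db="pubmed", rettype="xml", retmode="xml")
            if self._history is not None:
                webenv, qkey = self._history
                kwargs.update(webenv=webenv, query_key=qkey, retmax=len(ids))
            else:
                kwargs["id"] = ",".join(ids)
            with self._entrez.efetch(**kwargs) as handle:
                xml = handle.read()
        except Exception as exc:
            raise BackendError(f"eFetch failed: {exc}") from exc
        if isinstance(xml, str):
            xml = xml.encode("utf-8")
        return parse_medline_xml(xml)
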
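"""Local HTTP service mirroring the two search modes and the BioC fetch.

Stdlib http.server; JSON payloads. Endpoints:

    GET /fetch?ids=ID1,ID2            (<= 50 ids; oversize flagged attachment)
    GET /search/query?q=...&code=...&top=N
    GET /search/table?article=...&file=...
"""

from __future__ import annotations

import json
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

from .bioc import BioCDocument
from .embedding import Encoder
from .index import (
    IndexEntry,
    NeighborList,
    NotFoundError,
    UnknownCodeError,
    fetch_sm,
    search_by_query,
    search_by_table,
)


class ServiceState:
    def __init__(
        self,
        entries: list[IndexEntry],
        neighbors: dict,
        encoder: Encoder,
        corpus_store: dict[str, list[BioCDocument]],
    ) -> None:
        self.entries = entries
        self.neighbors = neighbors
        self.encoder = encoder
        self.corpus_store = corpus_store


def _handler_for(state: ServiceState):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args) -> None:  # quiet by default
            pass

        def _send(self, status: int, obj: dict) -> None:
            body = json.dumps(obj, ensure_ascii=False).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json; charset=utf-8")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self) -> None:  # noqa: N802 (http.server API)
            url = urlparse(self.path)
            q = {k: v[0] for k, v in parse_qs(url.query).items()}
            try:
                if url.path == "/fetch":
                    ids = [i for i in q.get("ids", "").split(",") if i]
                    result = fetch_sm(state.corpus_store, ids)
                    self._send(
                        200,
                        {
                            "attachment": result.attachment,
                            "missing": result.missing,
                            "size_bytes": result.size_bytes,
                            "collection": json.loads(result.body),
                        },
                    )
                elif url.path == "/search/query":
                    results = search_by_query(
                        state.entries,
                        state.encoder,
                        q.get("q", ""),
                        q.get("code", ""),
                        top_n=int(q.get("top", "10")),
                    )
                    self._send(
                        200,
                        {
                            "results": [
                                {
                                    "article_id": r.article_id,
                                    "best_table": list(r.best_table),
                                    "score": r.score,
                                }
                                for r in results
                            ]
                        },
                    )
                elif url.path == "/search/table":
                    ranked = search_by_table(
                        state.entries,
                        state.neighbors,
                        q.get("article", ""),
                        q.get("file", ""),
                    )
                    self._send(
                        200,
                        {"results": [{"key": list(k), "score": s} for k, s in ranked]},
                    )
                else:
                    self._send(404, {"error": f"unknown endpoint {url.path}"})
            except (ValueError, UnknownCodeError) as exc:
                self._send(400, {"error": str(exc)})
            except NotFoundError as exc:
                self._send(404, {"error": str(exc)})

    return Handler


def make_server(state: ServiceState, port: int = 0) -> ThreadingHTTPServer:
    """Bind (port 0 = ephemeral); caller runs serve_forever/shutdown."""
    return ThreadingHTTPServer(("127.0.0.1", port), _handler_for(state))
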
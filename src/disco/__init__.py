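"""Data-aggregation engine: registered resources are harvested on a
schedule, diffed against production, versioned with reverse deltas, and
released through a curated pending→production lifecycle feeding
materialized multi-resource views.
"""

from __future__ import annotations

from datetime import datetime, timezone
from typing import Callable

from .concept_mapper import ConceptMapper
from .dashboards import Dashboards
from .lifecycle import Lifecycle
from .registry import Registry
from .scheduler import Scheduler
from .staging import Staging
from .store import Store
from .version_store import VersionStore
from .views import Views

__version__ = "0.1.0"

__all__ = ["Disco", "Store", "__version__"]


class Disco:
    """Facade wiring every subsystem around one embedded database."""

    def __init__(self, db_path: str = ":memory:",
                 clock: Callable[[], datetime] | None = None):
        clock = clock or (lambda: datetime.now(timezone.utc))
        self.clock = clock
        self.store = Store(db_path)
        self.registry = Registry(self.store, clock)
        self.staging = Staging(self.store, clock)
        self.versions = VersionStore(self.store, clock)
        self.views = Views(self.store, self.versions, clock)
        self.lifecycle = Lifecycle(
            self.store, self.registry, self.staging, self.versions,
            views=self.views, clock=clock,
        )
        self.scheduler = Scheduler(self.store, self.registry, self.lifecycle)
        self.mapper = ConceptMapper(self.store, self.versions)
        self.dashboards = Dashboards(
            self.store, self.registry, self.scheduler, self.views
        )

    def close(self) -> None:
        self.store.close()
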
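"""Dashboard reports: pure reads over warehouse state.

Rendering never mutates the store.  Status icons are ASCII markers:
``[P]`` pending, ``[=]`` unchanged, ``[ok]`` healthy, ``[!]`` problem.
"""

from __future__ import annotations


from .errors import NotFoundError
from .store import Store

STATUS_MARKERS = {
    "pending_clock": "[P]",
    "unchanged_equals": "[=]",
    "ok": "[ok]",
    "problem": "[!]",
}


class Dashboards:
    def __init__(self, store: Store, registry, scheduler, views=None):
        self.store = store
        self.registry = registry
        self.scheduler = scheduler
        self.views = views

    # -- data source dashboard ----------------------------------------

    def _current_status(self, resource_id: str) -> tuple[str, str | None]:
        """Marker plus the date of the most recent activity."""
        staged = self.store.conn.execute(
            "SELECT status, created_at FROM staged_versions"
            " WHERE resource_id = ? AND status IN ('pending', 'problem',"
            " 'approved', 'scheduled') ORDER BY id DESC LIMIT 1",
            (resource_id,),
        ).fetchone()
        if staged is not None:
            marker = "problem" if staged["status"] == "problem" else "pending_clock"
            return marker, staged["created_at"]
        run = self.store.conn.execute(
            "SELECT outcome, finished_at FROM runs WHERE resource_id = ?"
            " ORDER BY id DESC LIMIT 1",
            (resource_id,),
        ).fetchone()
        if run is not None:
            if run["outcome"] == "unchanged":
                return "unchanged_equals", run["finished_at"]
            if run["outcome"] == "failed":
                return "problem", run["finished_at"]
        return "ok", run["finished_at"] if run else None

    def data_source_dashboard(self) -> list[dict]:
        """One row per resource+service with production and current state."""
        rows = []
        for res in self.registry.list_resources().items:
            for service in sorted(res.services):
                prod = self.store.conn.execute(
                    "SELECT version, promoted_at FROM production"
                    " WHERE resource_id = ? AND service = ?",
                    (res.nif_id, service),
                ).fetchone()
                promo = self.store.conn.execute(
                    "SELECT record_count FROM promotions"
                    " WHERE resource_id = ? AND service = ?"
                    " ORDER BY id DESC LIMIT 1",
                    (res.nif_id, service),
                ).fetchone()
                marker, current_date = self._current_status(res.nif_id)
                rows.append(
                    {
                        "nif_id": res.nif_id,
                        "name": res.name,
                        "service": service,
                        "production_version": prod["version"] if prod else None,
                        "production_date": prod["promoted_at"] if prod else None,
                        "production_records": promo["record_count"] if promo else None,
                        "current_date": current_date,
                        "status": marker,
                        "status_icon": STATUS_MARKERS[marker],
                    }
                )
        rows.sort(key=lambda r: (r["nif_id"], r["service"]))
        return rows

    # -- update-frequency report --------------------------------------

    def update_frequency_report(self) -> dict:
        counts = {"weekly": 0, "biweekly": 0, "monthly": 0, "adhoc": 0}
        for res in self.registry.list_resources().items:
            if "interop" not in res.services:
                continue
            counts[self.scheduler.frequency_of(res.nif_id)] += 1
        counts["total"] = sum(counts.values())
        return counts

    # -- growth report -------------------------------------------------

    def growth_report(self, resource_id: str | None = None) -> list[dict]:
        """Record counts at promotion times (one point per promotion)."""
        if resource_id is not None:
            if self.registry._get_or_none(resource_id) is None:
                raise NotFoundError(f"resource {resource_id!r} is not registered")
            rows = self.store.conn.execute(
                "SELECT promoted_at, record_count, version FROM promotions"
                " WHERE resource_id = ? ORDER BY id",
                (resource_id,),
            ).fetchall()
            return [
                {"date": r["promoted_at"], "version": r["version"],
                 "records": r["record_count"]}
                for r in rows
            ]
        rows = self.store.conn.execute(
            "SELECT resource_id, promoted_at, record_count FROM promotions ORDER BY id"
        ).fetchall()
        latest: dict[str, int] = {}
        series = []
        for r in rows:
            latest[r["resource_id"]] = r["record_count"]
            series.append({"date": r["promoted_at"], "records": sum(latest.values())})
        return series

    # -- views dashboard -----------------------------------------------

    def views_dashboard(self) -> list[dict]:
        if self.views is None:
            return []
        out = []
        for v in self.views.list_views():
            out.append(
                {
                    "view": v.view_name,
                    "members": [m.resource_id for m in v.members],
                    "beta_materialization": v.beta_mat,
                    "beta_at": v.beta_at,
                    "production_materialization": v.prod_mat,
                    "production_at": v.prod_at,
                    "beta_newer": v.beta_mat > v.prod_mat,
                    "failed": v.failed,
                }
            )
        return out
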
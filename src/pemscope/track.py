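"""Longitudinal tracking of cells across imaging days.

Cells observed on consecutive days in a registered coordinate frame are
matched by greedy mutual-nearest-neighbor linking within a displacement
bound; PEM retention, per-day PEM proportions and gain/loss event tables
are derived from the linked tables.  "Retained" means the day-0 PEM's
microglia is still within the association radius of *a* pericyte (not
necessarily its original partner); the strict same-partner variant is
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associate import AssociationCriteria, classify_pem
from .synthdata import MICROGLIA, PERICYTE, TimeSeriesScene

logger = logging.getLogger("pemscope.track")


@dataclass
class Links:
    """One-to-one links between two daily tables (per cell type)."""

    pairs: pd.DataFrame            # columns: id_a, id_b, distance_um
    appeared: list                 # ids in b with no partner in a
    disappeared: list              # ids in a with no partner in b

    def mapping(self) -> dict:
        return dict(zip(self.pairs.id_a.astype(int),
                        self.pairs.id_b.astype(int)))


def match_across_days(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      max_displacement: float = 15.0,
                      criteria: AssociationCriteria | None = None) -> Links:
    """Greedy mutual-nearest-neighbor matching within ``max_displacement``.

    Links are formed in ascending distance order (ties broken by lower id
    in table a, then table b); each cell participates in at most one link;
    only same-type cells are matched.  Unmatched cells are flagged
    appeared/disappeared.
    """
    criteria = criteria or AssociationCriteria()
    pairs, appeared, disappeared = [], [], []
    from .associate import reference_coords

    for ctype in (MICROGLIA, PERICYTE):
        a = table_a[table_a.cell_type == ctype].sort_values("cell_id")
        b = table_b[table_b.cell_type == ctype].sort_values("cell_id")
        if not len(a) or not len(b):
            disappeared += a.cell_id.astype(int).tolist()
            appeared += b.cell_id.astype(int).tolist()
            continue
        pa = reference_coords(a, criteria)
        pb = reference_coords(b, criteria)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        ids_a = a.cell_id.to_numpy(dtype=int)
        ids_b = b.cell_id.to_numpy(dtype=int)
        cand = [(d[i, j], ids_a[i], ids_b[j], i, j)
                for i in range(len(a)) for j in range(len(b))
                if d[i, j] <= max_displacement]
        cand.sort()
        used_a: set = set()
        used_b: set = set()
        for dist, ia, ib, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append(dict(id_a=ia, id_b=ib, distance_um=float(dist),
                              cell_type=ctype))
        disappeared += [int(ids_a[i]) for i in range(len(a))
                        if i not in used_a]
        appeared += [int(ids_b[j]) for j in range(len(b)) if j not in used_b]

    return Links(pairs=pd.DataFrame(
        pairs, columns=["id_a", "id_b", "distance_um", "cell_type"]),
        appeared=sorted(appeared), disappeared=sorted(disappeared))


def match_series(series: TimeSeriesScene,
                 max_displacement: float = 15.0) -> dict:
    """Links for every consecutive day pair."""
    out = {}
    for da, db in zip(series.days[:-1], series.days[1:]):
        out[(da, db)] = match_across_days(series.cells_by_day[da],
                                          series.cells_by_day[db],
                                          max_displacement)
    return out


def _labeled_by_day(series: TimeSeriesScene,
                    criteria: AssociationCriteria) -> dict:
    return {day: classify_pem(series.cells_by_day[day], criteria,
                              network=series.networks_by_day.get(day))
            for day in series.days}


def _chain(links: dict, days: list, day_target: int, cell_id: int):
    """Follow links day0 -> target; None if the chain breaks."""
    cur = cell_id
    for da, db in zip(days, days[1:]):
        if db > day_target:
            break
        m = links[(da, db)].mapping()
        if cur not in m:
            return None
        cur = m[cur]
        if db == day_target:
            return cur
    return cur if day_target == days[0] else None


def pem_retention(series: TimeSeriesScene, max_displacement: float = 15.0,
                  criteria: AssociationCriteria | None = None,
                  day0_pem: list | None = None) -> pd.DataFrame:
    """Fraction of day-0 PEM still adjacent to a pericyte on each later day.

    A day-0 PEM whose microglia cannot be followed to a later day counts as
    not retained on that day.  ``frac_same_partner`` additionally requires
    adjacency (within r_assoc) to the tracked original partner pericyte.
    """
    criteria = criteria or AssociationCriteria(use_nucleus_center=False)
    labeled = _labeled_by_day(series, criteria)
    links = match_series(series, max_displacement)
    day0 = series.days[0]
    lab0 = labeled[day0]
    if day0_pem is None:
        day0_pem = lab0.loc[(lab0.cell_type == MICROGLIA) & lab0.is_pem,
                            "cell_id"].astype(int).tolist()
    partner0 = dict(zip(lab0.cell_id.astype(int),
                        lab0.nearest_pericyte_id))

    rows = [dict(day=day0, n_day0_pem=len(day0_pem), frac_any=1.0,
                 frac_same_partner=1.0)]
    for day in series.days[1:]:
        lab = labeled[day]
        pem_now = dict(zip(lab.cell_id.astype(int), lab.is_pem))
        near_now = dict(zip(lab.cell_id.astype(int),
                            lab.nearest_pericyte_distance_um))
        partner_now = dict(zip(lab.cell_id.astype(int),
                               lab.nearest_pericyte_id))
        kept_any = kept_same = 0
        for mid in day0_pem:
            cur = _chain(links, series.days, day, mid)
            if cur is None or not pem_now.get(cur, False):
                continue
            kept_any += 1
            # original partner pericyte tracked forward
            p0 = partner0.get(mid)
            if p0 is None or np.isnan(p0):
                continue
            p_cur = _chain(links, series.days, day, int(p0))
            if p_cur is not None and partner_now.get(cur) == p_cur:
                kept_same += 1
            elif p_cur is not None:
                # adjacent to the original partner even if not the nearest
                row = lab[lab.cell_id == cur]
                prow = lab[lab.cell_id == p_cur]
                if len(row) and len(prow):
                    from .associate import reference_coords
                    dd = float(np.linalg.norm(
                        reference_coords(row, criteria)[0] -
                        reference_coords(prow, criteria)[0]))
                    if criteria.within(dd):
                        kept_same += 1
        n = len(day0_pem)
        rows.append(dict(day=day, n_day0_pem=n,
                         frac_any=kept_any / n if n else np.nan,
                         frac_same_partner=kept_same / n if n else np.nan))
    return pd.DataFrame(rows)


def pem_proportion_by_day(series: TimeSeriesScene,
                          criteria: AssociationCriteria | None = None
                          ) -> pd.DataFrame:
    """Percentage of pericytes with a PEM on each imaging day."""
    criteria = criteria or AssociationCriteria(use_nucleus_center=False)
    labeled = _labeled_by_day(series, criteria)
    rows = []
    for day in series.days:
        lab = labeled[day]
        peri = lab[lab.cell_type == PERICYTE]
        rows.append(dict(day=day, n_pericytes=len(peri),
                         pct_pericytes_with_pem=100.0 * peri.has_pem.mean()
                         if len(peri) else np.nan))
    return pd.DataFrame(rows)


def pem_proportion_anova(tables: list) -> dict | None:
    """Repeated-measures comparison of per-scene %pericytes-with-PEM across
    days, delegated to statsmodels' AnovaRM.  ``tables`` is one
    pem_proportion_by_day frame per scene."""
    if len(tables) < 2:
        return None
    long = pd.concat([t.assign(scene=i) for i, t in enumerate(tables)])
    try:
        from statsmodels.stats.anova import AnovaRM
        res = AnovaRM(long, depvar="pct_pericytes_with_pem",
                      subject="scene", within=["day"]).fit()
        row = res.anova_table.iloc[0]
        return {"F": float(row["F Value"]), "p_value": float(row["Pr > F"])}
    except Exception as exc:  # degenerate designs (constant columns etc.)
        logger.warning("repeated-measures ANOVA unavailable: %s", exc)
        return None


def gain_loss_events(series: TimeSeriesScene,
                     max_displacement: float = 15.0,
                     criteria: AssociationCriteria | None = None) -> dict:
    """Per-pericyte has_pem transition sequences and their classification.

    Each pericyte tracked across all days gets a category: ``stable``
    (always has a PEM), ``none`` (never), ``gained`` (single false->true
    transition), ``lost`` (single true->false), ``transient`` (multiple
    transitions).  Every transition is logged as an event row with its day
    stamp.  Pericytes that cannot be tracked across all days are excluded
    and logged.
    """
    criteria = criteria or AssociationCriteria(use_nucleus_center=False)
    labeled = _labeled_by_day(series, criteria)
    links = match_series(series, max_displacement)
    day0 = series.days[0]
    peri0 = labeled[day0]
    peri0 = peri0[peri0.cell_type == PERICYTE]

    events, cats = [], []
    for _, p in peri0.iterrows():
        pid = int(p.cell_id)
        seq = []
        ok = True
        for day in series.days:
            cur = _chain(links, series.days, day, pid)
            if cur is None:
                ok = False
                break
            lab = labeled[day]
            row = lab[(lab.cell_id == cur) & (lab.cell_type == PERICYTE)]
            if not len(row):
                ok = False
                break
            seq.append(bool(row.has_pem.iloc[0]))
        if not ok:
            logger.info("pericyte %d unmatched across days, excluded", pid)
            continue
        transitions = [(series.days[i], series.days[i + 1], seq[i], seq[i + 1])
                       for i in range(len(seq) - 1) if seq[i] != seq[i + 1]]
        for da, db, was, now in transitions:
            events.append(dict(pericyte_id=pid, day=db,
                               event="gain" if now else "loss"))
        if not transitions:
            cat = "stable" if seq[0] else "none"
        elif len(transitions) == 1:
            cat = "gained" if transitions[0][3] else "lost"
        else:
            cat = "transient"
        cats.append(dict(pericyte_id=pid, category=cat,
                         has_pem_sequence="".join("T" if s else "F"
                                                  for s in seq)))
    return {"events": pd.DataFrame(
        events, columns=["pericyte_id", "day", "event"]),
        "pericytes": pd.DataFrame(
            cats, columns=["pericyte_id", "category", "has_pem_sequence"])}
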
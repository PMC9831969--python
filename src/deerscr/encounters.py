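"""Encounter histories and survey summaries.

Detections of identified individuals at sampling plots are organised into
per-session binary individual x trap x occasion arrays (a proximity
detector: an individual can be detected at several traps in one occasion,
but repeats at the same trap-occasion collapse to a single 1).  The survey
summary reproduces the usual non-invasive-survey bookkeeping: individuals
by sex, sex ratio, detections, recapture-frequency distribution and
recapture rate, plus genotyping success when sample counts are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import TrapArray

__all__ = [
    "DetectionRecord",
    "SessionEncounters",
    "EncounterArray",
    "build_encounter_array",
    "survey_summary",
    "recapture_distances",
    "read_detection_records",
    "write_detection_records",
]


@dataclass(frozen=True)
class DetectionRecord:
    """One genotyped sample assigned to an individual at a trap-occasion."""

    individual: str
    sex: str  # 'F' | 'M' | 'unknown'
    trap: str
    occasion: int  # 1-based within session
    session: str


@dataclass
class SessionEncounters:
    """Binary detections for one closed session."""

    session: str
    y: np.ndarray  # (n_individuals, n_traps, n_occasions) in {0,1}
    individuals: list[str]
    sex: np.ndarray  # per-individual 'F'/'M'/'unknown'
    trap_ids: list[str]
    n_occasions: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("encounter entries must be 0/1")
        if (self.y.reshape(self.y.shape[0], -1).sum(axis=1) == 0).any():
            raise ValueError("every individual must have at least one detection")


@dataclass
class EncounterArray:
    """Multi-session encounter data; cross-session identity kept separately."""

    sessions: dict[str, SessionEncounters]
    cross_session: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, session: str) -> SessionEncounters:
        return self.sessions[session]

    @property
    def session_ids(self) -> list[str]:
        return list(self.sessions)


def build_encounter_array(records: list[DetectionRecord],
                          traps: TrapArray,
                          occasions_per_session: dict[str, int]) -> EncounterArray:
    """Collapse detection records into per-session binary arrays.

    Individuals are indexed separately inside each session (a deer seen in
    both years contributes an independent history to each); the
    ``cross_session`` map records which sessions each individual appears in.
    """
    trap_ids = [str(t) for t in traps.ids]
    trap_index = {t: i for i, t in enumerate(trap_ids)}
    sessions: dict[str, SessionEncounters] = {}
    cross: dict[str, list[str]] = {}
    by_session: dict[str, list[DetectionRecord]] = {}
    for r in records:
        if r.session not in occasions_per_session:
            raise ValueError(f"unknown session {r.session!r}")
        if str(r.trap) not in trap_index:
            raise ValueError(f"unknown trap id {r.trap!r}")
        K = occasions_per_session[r.session]
        if not (1 <= r.occasion <= K):
            raise ValueError(
                f"occasion {r.occasion} out of range 1..{K} for session {r.session}")
        by_session.setdefault(r.session, []).append(r)
        lst = cross.setdefault(r.individual, [])
        if r.session not in lst:
            lst.append(r.session)

    for session in occasions_per_session:
        recs = by_session.get(session, [])
        inds: list[str] = []
        sex: dict[str, str] = {}
        for r in recs:
            if r.individual not in inds:
                inds.append(r.individual)
                sex[r.individual] = r.sex
        y = np.zeros((len(inds), len(trap_ids), occasions_per_session[session]), dtype=int)
        ind_index = {ind: i for i, ind in enumerate(inds)}
        for r in recs:
            y[ind_index[r.individual], trap_index[str(r.trap)], r.occasion - 1] = 1
        if inds:
            sessions[session] = SessionEncounters(
                session=session, y=y, individuals=inds,
                sex=np.array([sex[i] for i in inds]),
                trap_ids=trap_ids, n_occasions=occasions_per_session[session],
            )
    return EncounterArray(sessions=sessions, cross_session=cross)


def survey_summary(array: EncounterArray,
                   n_collected: dict[str, int] | None = None,
                   n_genotyped: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-session survey bookkeeping.

    A *detection* is a distinct (individual, trap, occasion) triple after
    binarisation; an individual is *recaptured* when detected more than
    once.  Percentages are returned as proportions (0-1); ratios as plain
    quotients.
    """
    rows = []
    for session, enc in array.sessions.items():
        det_per_ind = enc.y.reshape(enc.y.shape[0], -1).sum(axis=1)
        is_m = enc.sex == "M"
        is_f = enc.sex == "F"
        n = len(enc.individuals)
        n_m, n_f = int(is_m.sum()), int(is_f.sum())
        recap = det_per_ind > 1
        freq: dict[int, int] = {}
        for k in det_per_ind[recap]:
            # "recaptured k times" = detected k+1 times total
            freq[int(k) - 1] = freq.get(int(k) - 1, 0) + 1
        row = {
            "session": session,
            "n_individuals": n,
            "n_males": n_m,
            "n_females": n_f,
            "sex_ratio_mf": n_m / n_f if n_f else np.nan,
            "total_detections": int(det_per_ind.sum()),
            "detections_males": int(det_per_ind[is_m].sum()),
            "detections_females": int(det_per_ind[is_f].sum()),
            "n_detected_once": int((~recap).sum()),
            "n_recaptured": int(recap.sum()),
            "recapture_rate": float(recap.sum() / n) if n else np.nan,
            "recapture_rate_males": float(recap[is_m].sum() / n_m) if n_m else np.nan,
            "recapture_rate_females": float(recap[is_f].sum() / n_f) if n_f else np.nan,
            "recapture_frequencies": dict(sorted(freq.items())),
        }
        if n_collected and n_genotyped and session in n_collected:
            row["n_collected"] = n_collected[session]
            row["n_genotyped"] = n_genotyped[session]
            row["genotyping_success"] = n_genotyped[session] / n_collected[session]
        rows.append(row)
    return pd.DataFrame(rows)


def recapture_distances(records: list[DetectionRecord],
                        traps: TrapArray) -> pd.DataFrame:
    """Distances between chronologically consecutive detections, per sex.

    Within an occasion detection order is undefined; detections sort by
    (occasion, trap id) to make consecutive pairs deterministic.  Returns one
    row per sex with mean and min-max range (m); empty when no individual
    was detected twice.
    """
    xy = {str(t): (x, y) for t, x, y in zip(traps.ids, traps.x, traps.y)}
    per_sex: dict[str, list[float]] = {}
    by_ind: dict[tuple[str, str], list[DetectionRecord]] = {}
    for r in records:
        by_ind.setdefault((r.session, r.individual), []).append(r)
    for (_, _), recs in sorted(by_ind.items()):
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=lambda r: (r.occasion, str(r.trap)))
        sex = recs[0].sex
        for a, b in zip(recs[:-1], recs[1:]):
            (x1, y1), (x2, y2) = xy[str(a.trap)], xy[str(b.trap)]
            per_sex.setdefault(sex, []).append(float(np.hypot(x2 - x1, y2 - y1)))
    if not per_sex:
        import warnings

        warnings.warn("no recaptures: recapture distances are undefined")
        return pd.DataFrame(columns=["sex", "n", "mean_m", "min_m", "max_m"])
    rows = [
        {"sex": s, "n": len(d), "mean_m": float(np.mean(d)),
         "min_m": float(np.min(d)), "max_m": float(np.max(d))}
        for s, d in sorted(per_sex.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def read_detection_records(path) -> list[DetectionRecord]:
    df = pd.read_csv(path, comment="#",
                     dtype={"individual": str, "trap": str, "session": str})
    return [
        DetectionRecord(
            individual=r.individual, sex=r.sex, trap=r.trap,
            occasion=int(r.occasion), session=r.session,
        )
        for r in df.itertuples()
    ]


def write_detection_records(records: list[DetectionRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
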
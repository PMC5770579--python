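"""30-day tailored message schedule with weekly activity links.

Cadence is stage-dependent but deterministic: each stage maps to a fixed
gap in days (configurable, always within 1–3).  The first message of
each 7-day window in days 1–28 carries a link to one of the four web
activities, so every schedule has exactly four linked messages; days
29–30 never carry one.  Template choice among equally tagged candidates
is the only seeded randomness: candidates are shuffled once per pool and
then cycled, so no template id repeats before every matching template
has been used.
"""

from __future__ import annotations

import csv
import random
from datetime import date, time, timedelta
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .content import Channel, ContentLibrary, ContentTemplate
from .errors import AppointmentError, MissingTemplateError, ScheduleError
from .tailoring import Purpose, Stage, TailoredSession, Track

HORIZON_DAYS = 30
PAC_WINDOWS = ((1, 7), (8, 14), (15, 21), (22, 28))

#: Days between consecutive messages, by quit stage (must stay in 1..3).
DEFAULT_STAGE_GAPS: dict[Stage, int] = {
    Stage.PRECONTEMPLATION: 3,
    Stage.CONTEMPLATION: 2,
    Stage.PREPARATION: 1,
    Stage.ACTION: 1,
    Stage.MAINTENANCE: 2,
}

DEFAULT_SEND_TIME = time(10, 0)
DEFAULT_REMINDER_LEAD_DAYS = (3, 1)

REMINDER_TEMPLATE_ID = "builtin-appointment-reminder"
REMINDER_BODY = "You have a visit with your provider on {date}. Please be there."
RESTAGE_TEMPLATE_ID = "builtin-stage-assessment"
RESTAGE_BODY = "Quick check in: tap this link to answer two short questions: {link}"
STAGE_ASSESSMENT_LINK = "https://example.invalid/pac/stage-check"

PAC_LINKS = tuple(
    f"https://example.invalid/pac/activity-{i}" for i in range(1, 5)
)


class ScheduledMessage(BaseModel):
    day_offset: int = Field(ge=1, le=HORIZON_DAYS)
    send_time: time = DEFAULT_SEND_TIME
    template_id: str
    body: str
    pac_link: bool = False
    reminder: bool = False


class MessageSchedule(BaseModel):
    patient_name: Optional[str] = None
    start_date: date
    seed: int
    messages: list[ScheduledMessage]
    appointments: list[date] = Field(default_factory=list)

    def send_date(self, message: ScheduledMessage) -> date:
        return self.start_date + timedelta(days=message.day_offset - 1)

    def pac_messages(self) -> list[ScheduledMessage]:
        return [m for m in self.messages if m.pac_link]

    def gaps(self) -> list[int]:
        """Gaps between consecutive non-reminder messages."""
        offsets = [m.day_offset for m in self.messages if not m.reminder]
        return [b - a for a, b in zip(offsets, offsets[1:])]

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MessageSchedule":
        return cls.model_validate_json(text)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["date", "time", "body", "pac_link", "reminder"])
            for m in self.messages:
                writer.writerow(
                    [
                        self.send_date(m).isoformat(),
                        m.send_time.isoformat("minutes"),
                        m.body,
                        int(m.pac_link),
                        int(m.reminder),
                    ]
                )


class _Rotation:
    """Cycle through a seeded shuffle of a template pool."""

    def __init__(self, pool: Sequence[ContentTemplate], rng: random.Random):
        self._order = list(pool)
        rng.shuffle(self._order)
        self._next = 0

    def take(self) -> ContentTemplate:
        template = self._order[self._next % len(self._order)]
        self._next += 1
        return template


def _message_days(gap: int) -> list[int]:
    if gap not in (1, 2, 3):
        raise ScheduleError(f"configured gap {gap} outside 1..3")
    return list(range(1, HORIZON_DAYS + 1, gap))


def _pac_days(days: Sequence[int]) -> set[int]:
    chosen = set()
    for lo, hi in PAC_WINDOWS:
        for d in days:
            if lo <= d <= hi:
                chosen.add(d)
                break
    return chosen


def build_schedule(
    session: TailoredSession,
    library: ContentLibrary,
    start_date: date,
    seed: int,
    *,
    stage_gaps: dict[Stage, int] | None = None,
    send_time: time = DEFAULT_SEND_TIME,
) -> MessageSchedule:
    """Deterministic 30-day schedule tailored to the session."""
    if session.track is Track.SCREENED_OUT:
        raise ScheduleError("cannot schedule messages for a screened-out session")
    assert session.target_drug is not None and session.quit_stage is not None
    gaps = stage_gaps or DEFAULT_STAGE_GAPS
    gap = gaps[session.quit_stage]
    days = _message_days(gap)
    pac_days = _pac_days(days)

    risk = next(
        a.category for a in session.assessments if a.substance == session.target_drug
    )
    criteria = dict(
        channel=Channel.SMS,
        drug=session.target_drug,
        risk=risk,
        stage=session.quit_stage,
        purpose=Purpose.QUIT,
    )
    plain_pool = library.matching(**criteria, link_slot=False)
    pac_pool = library.matching(**criteria, link_slot=True)
    if not plain_pool:
        raise MissingTemplateError(f"no sms template for {criteria}")
    if not pac_pool:
        raise MissingTemplateError(f"no link-slot sms template for {criteria}")

    rng = random.Random(seed)
    plain_rotation = _Rotation(plain_pool, rng)
    pac_rotation = _Rotation(pac_pool, rng)

    context = {
        "drug": session.target_drug.display_name,
        "risk": risk.value,
        "stage": session.quit_stage.value,
        "goal": session.goal_plan.chosen_goal if session.goal_plan else "your goal",
    }

    messages = []
    pac_index = 0
    for day in days:
        if day in pac_days:
            template = pac_rotation.take()
            body = template.resolve({**context, "link": PAC_LINKS[pac_index]})
            pac_index += 1
            messages.append(
                ScheduledMessage(
                    day_offset=day,
                    send_time=send_time,
                    template_id=template.id,
                    body=body,
                    pac_link=True,
                )
            )
        else:
            template = plain_rotation.take()
            messages.append(
                ScheduledMessage(
                    day_offset=day,
                    send_time=send_time,
                    template_id=template.id,
                    body=template.resolve(context),
                )
            )
    return MessageSchedule(
        patient_name=session.patient_name,
        start_date=start_date,
        seed=seed,
        messages=messages,
    )


def add_appointment_reminders(
    schedule: MessageSchedule,
    appointment_date: date,
    *,
    lead_days: Sequence[int] = DEFAULT_REMINDER_LEAD_DAYS,
) -> MessageSchedule:
    """Insert reminder messages on the lead days before an appointment.

    Reminders are pure insertions: the base cadence is never altered.
    Re-adding the same appointment is a no-op.
    """
    offset = (appointment_date - schedule.start_date).days + 1
    if not 1 <= offset <= HORIZON_DAYS:
        raise AppointmentError(
            f"appointment {appointment_date} outside the {HORIZON_DAYS}-day horizon"
        )
    if appointment_date in schedule.appointments:
        return schedule
    reminder_days = sorted(
        offset - lead for lead in lead_days if offset - lead >= 1
    )
    if not reminder_days:
        raise AppointmentError(
            f"no lead time before appointment on day {offset}"
        )
    reminders = [
        ScheduledMessage(
            day_offset=day,
            template_id=REMINDER_TEMPLATE_ID,
            body=REMINDER_BODY.format(date=appointment_date.isoformat()),
            reminder=True,
        )
        for day in reminder_days
    ]
    merged = sorted(
        [*schedule.messages, *reminders],
        key=lambda m: (m.day_offset, m.reminder),
    )
    return schedule.model_copy(
        update={
            "messages": merged,
            "appointments": [*schedule.appointments, appointment_date],
        }
    )


def add_stage_assessment(schedule: MessageSchedule) -> MessageSchedule:
    """Append one stage-assessment message (provider restage request)."""
    last_day = max((m.day_offset for m in schedule.messages), default=0)
    day = min(last_day + 1, HORIZON_DAYS)
    message = ScheduledMessage(
        day_offset=day,
        template_id=RESTAGE_TEMPLATE_ID,
        body=RESTAGE_BODY.format(link=STAGE_ASSESSMENT_LINK),
        reminder=True,
    )
    merged = sorted(
        [*schedule.messages, message], key=lambda m: (m.day_offset, m.reminder)
    )
    return schedule.model_copy(update={"messages": merged})
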
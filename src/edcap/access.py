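"""Group-based access control.

Data is owned by *groups* (a clinical service, a research study).  Users
hold *memberships* in groups, each membership carrying its own permission
flags; a group may additionally be permitted to see data from an explicit
list of other groups.  Visibility is one-step and directional: A seeing B
and B seeing C does not grant A sight of C, and B does not automatically
see A.  Superusers bypass group visibility entirely; "patient-locked"
users (single-patient mode) can reach only the one subject they belong to.

Everything here is pure logic over small dataclasses, so the same
decisions can be exercised against brute-force oracles in tests and then
applied by the record store and the export layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .policy import IdPolicy

__all__ = [
    "UserStatus",
    "Group",
    "User",
    "Membership",
    "Decision",
    "ACTION_FLAGS",
    "visible_groups",
    "authorize_view",
    "authorize_action",
]


class UserStatus(str, Enum):
    STAFF = "staff"
    SUPERUSER = "superuser"
    PATIENT_LOCKED = "patient_locked"


@dataclass(frozen=True)
class Group:
    group_id: int
    name: str
    upload_policy: IdPolicy
    finalize_policy: IdPolicy
    can_see_groups: frozenset[int] = frozenset()


@dataclass(frozen=True)
class User:
    user_id: int
    username: str
    status: UserStatus = UserStatus.STAFF
    # Identifier (linking ID number value) of the one patient a
    # patient-locked user belongs to; present iff status is PATIENT_LOCKED.
    locked_patient_key: Optional[int] = None

    def __post_init__(self):
        locked = self.status is UserStatus.PATIENT_LOCKED
        if locked != (self.locked_patient_key is not None):
            raise ValueError(
                "locked_patient_key present iff status is patient_locked"
            )

    @property
    def is_superuser(self) -> bool:
        return self.status is UserStatus.SUPERUSER


@dataclass(frozen=True)
class Membership:
    user_id: int
    group_id: int
    may_upload: bool = False
    may_register_devices: bool = False
    may_login_web: bool = False
    may_view_all_patients_unfiltered: bool = False
    may_dump: bool = False
    may_run_reports: bool = False
    may_add_notes: bool = False
    is_group_admin: bool = False


@dataclass(frozen=True)
class Decision:
    allowed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.allowed


# Action name -> membership flag consulted.
ACTION_FLAGS = {
    "upload": "may_upload",
    "register_device": "may_register_devices",
    "login_web": "may_login_web",
    "dump": "may_dump",
    "reports": "may_run_reports",
    "add_notes": "may_add_notes",
    "manage_users": "is_group_admin",
}


def visible_groups(
    user: User,
    memberships: Iterable[Membership],
    groups: Mapping[int, Group],
    groups_with_locked_patient: Optional[set[int]] = None,
) -> frozenset[int]:
    """Group IDs whose data the user may see at all.

    The union over the user's memberships of {group} plus the group's
    can_see list.  Superusers see every group.  Patient-locked users see
    only groups that actually hold their patient's records (pass these in
    via ``groups_with_locked_patient``).
    """
    if user.is_superuser:
        return frozenset(groups)
    visible: set[int] = set()
    for m in memberships:
        if m.user_id != user.user_id or m.group_id not in groups:
            continue
        visible.add(m.group_id)
        visible |= set(groups[m.group_id].can_see_groups) & set(groups)
    if user.status is UserStatus.PATIENT_LOCKED:
        if groups_with_locked_patient is None:
            groups_with_locked_patient = set()
        visible &= groups_with_locked_patient
    return frozenset(visible)


def _memberships_granting(
    user: User, memberships: Iterable[Membership], groups: Mapping[int, Group],
    owning_group: int,
) -> list[Membership]:
    """Memberships through which the owning group is visible to the user."""
    granting = []
    for m in memberships:
        if m.user_id != user.user_id or m.group_id not in groups:
            continue
        reachable = {m.group_id} | (set(groups[m.group_id].can_see_groups)
                                    & set(groups))
        if owning_group in reachable:
            granting.append(m)
    return granting


def authorize_view(
    user: User,
    memberships: Iterable[Membership],
    groups: Mapping[int, Group],
    owning_group: int,
    has_patient_filter: bool,
    record_patient_key: Optional[int] = None,
    groups_with_locked_patient: Optional[set[int]] = None,
) -> Decision:
    """Record-level read authorization.

    Allowed iff the owning group is visible to the user; and either a
    subject search criterion was applied or some membership granting that
    visibility carries the view-all-patients-unfiltered flag (so staff
    cannot browse every subject without searching); and, for
    patient-locked users, the record belongs to their one patient.
    """
    if user.is_superuser:
        return Decision(True, "superuser")
    memberships = list(memberships)
    if owning_group not in visible_groups(
        user, memberships, groups, groups_with_locked_patient
    ):
        return Decision(False, "owning group not visible to user")
    if user.status is UserStatus.PATIENT_LOCKED:
        if record_patient_key != user.locked_patient_key:
            return Decision(False, "user is locked to a different patient")
        return Decision(True, "locked patient's own record")
    if not has_patient_filter:
        granting = _memberships_granting(user, memberships, groups, owning_group)
        if not any(m.may_view_all_patients_unfiltered for m in granting):
            return Decision(
                False,
                "unfiltered multi-subject view requires the "
                "view-all-patients permission",
            )
    return Decision(True, "group visible")


def authorize_action(
    user: User,
    memberships: Iterable[Membership],
    action: str,
    group_id: int,
) -> Decision:
    """Permission-flag check for a named action within a group.

    Group admins may additionally manage users of their own group only;
    superusers may do anything.  Unknown actions are an error, not a deny.
    """
    if action not in ACTION_FLAGS:
        raise KeyError(f"unknown action: {action!r}")
    if user.is_superuser:
        return Decision(True, "superuser")
    flag = ACTION_FLAGS[action]
    for m in memberships:
        if m.user_id == user.user_id and m.group_id == group_id:
            if getattr(m, flag):
                return Decision(True, f"membership grants {action}")
            return Decision(False, f"membership lacks {flag}")
    return Decision(False, "no membership in group")
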
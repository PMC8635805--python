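"""Authentication security: irreversible password hashing, login throttling
with timing mimicry, session lifecycle, and the brute-force key-search
calculator.

Passwords are stored only as salted, adaptive (configurable-cost) PBKDF2
hashes in a self-describing format, so raising the cost factor later leaves
existing hashes verifiable.  Login failure handling is designed so an
attacker cannot distinguish a wrong password from a nonexistent username:
the nonexistent-user path performs exactly one dummy hash verification and
returns the same failure shape.  Accounts lock for increasing periods after
repeated failures.  Sessions are bound to the client IP, expire after
inactivity, and have their token regenerated at every login to prevent
session fixation.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import secrets
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta
from fractions import Fraction
from typing import Callable, Optional

from ._time import to_utc

__all__ = [
    "hash_password",
    "verify_password",
    "SessionToken",
    "LockoutState",
    "LoginFailure",
    "AuthConfig",
    "AuthService",
    "brute_force_mean_cycles",
    "brute_force_mean_time",
    "JULIAN_YEAR_SECONDS",
]

_SCHEME = "pbkdf2-sha256"
DEFAULT_COST = 50_000  # PBKDF2 iterations


def _b64(raw: bytes) -> str:
    return base64.b64encode(raw).decode("ascii").rstrip("=")


def _unb64(text: str) -> bytes:
    return base64.b64decode(text + "=" * (-len(text) % 4))


def hash_password(plaintext: str, cost: int = DEFAULT_COST) -> str:
    """Salted adaptive hash: ``$pbkdf2-sha256$<cost>$<salt>$<digest>``.

    The salt is fresh per call, so hashing the same plaintext twice yields
    different strings; the format is self-describing, so hashes created
    under an old cost factor still verify after the cost is raised.
    """
    if not plaintext:
        raise ValueError("empty password")
    if cost < 1:
        raise ValueError("cost must be >= 1")
    salt = secrets.token_bytes(16)
    digest = hashlib.pbkdf2_hmac("sha256", plaintext.encode("utf-8"), salt, cost)
    return f"${_SCHEME}${cost}${_b64(salt)}${_b64(digest)}"


def verify_password(plaintext: str, stored: str) -> bool:
    """Constant-time verification against a stored hash."""
    try:
        _, scheme, cost_s, salt_s, digest_s = stored.split("$")
        if scheme != _SCHEME:
            return False
        cost = int(cost_s)
        salt = _unb64(salt_s)
        expected = _unb64(digest_s)
    except (ValueError, TypeError):
        return False
    actual = hashlib.pbkdf2_hmac("sha256", plaintext.encode("utf-8"), salt, cost)
    return hmac.compare_digest(actual, expected)


# ------------------------------------------------------------------ sessions

@dataclass
class SessionToken:
    session_id: str
    token: str
    user_id: int
    created_at: datetime
    last_activity: datetime
    client_ip: str


@dataclass
class LockoutState:
    username: str
    consecutive_failures: int = 0
    locked_until: Optional[datetime] = None


@dataclass(frozen=True)
class LoginFailure:
    """Uniform failure shape for wrong password and unknown username."""

    reason: str = "invalid username or password"
    locked_until: Optional[datetime] = None


@dataclass
class AuthConfig:
    lockout_threshold: int = 7           # consecutive failures before locking
    lockout_base: timedelta = timedelta(minutes=1)
    lockout_cap: timedelta = timedelta(hours=24)
    inactivity_limit: timedelta = timedelta(minutes=30)
    max_password_age: Optional[timedelta] = None  # disabled unless configured
    hash_cost: int = DEFAULT_COST


def lockout_duration(config: AuthConfig, consecutive_failures: int
                     ) -> Optional[timedelta]:
    """Lock period after the given failure count: none below the threshold,
    then the base period doubling per further failure, capped."""
    if consecutive_failures < config.lockout_threshold:
        return None
    exponent = consecutive_failures - config.lockout_threshold
    duration = config.lockout_base * (2**exponent)
    return min(duration, config.lockout_cap)


class AuthService:
    """Login and session machinery over a user lookup.

    ``lookup`` maps a username to ``(user_id, password_hash,
    password_set_at)`` or None.  All time comes in through ``now``
    arguments, keeping behaviour deterministic under test.
    """

    def __init__(
        self,
        lookup: Callable[[str], Optional[tuple[int, str, Optional[datetime]]]],
        config: Optional[AuthConfig] = None,
        audit: Optional[Callable[[str, str], None]] = None,
    ):
        self.lookup = lookup
        self.config = config or AuthConfig()
        self.audit = audit or (lambda what, details: None)
        self.lockouts: dict[str, LockoutState] = {}
        self.sessions: dict[str, SessionToken] = {}
        self.verify_calls = 0  # instrumented so mimicry is testable
        # Dummy hash verified for nonexistent usernames, so that path does
        # the same cryptographic work as a real failed login.
        self._dummy_hash = hash_password("dummy-password", cost=self.config.hash_cost)

    # -- internals ---------------------------------------------------------

    def _verify(self, plaintext: str, stored: str) -> bool:
        self.verify_calls += 1
        return verify_password(plaintext, stored)

    def _state(self, username: str) -> LockoutState:
        return self.lockouts.setdefault(username, LockoutState(username))

    def _record_failure(self, username: str, now: datetime) -> LoginFailure:
        state = self._state(username)
        state.consecutive_failures += 1
        duration = lockout_duration(self.config, state.consecutive_failures)
        if duration is not None:
            state.locked_until = to_utc(now) + duration
        self.audit("login_failure", username)
        return LoginFailure()

    # -- public API --------------------------------------------------------

    def attempt_login(
        self, username: str, password: str, client_ip: str, now: datetime
    ) -> SessionToken | LoginFailure:
        now = to_utc(now)
        state = self._state(username)
        if state.locked_until is not None:
            if now < state.locked_until:
                self.audit("login_rejected_locked", username)
                return LoginFailure("account locked", state.locked_until)
            state.locked_until = None  # lock expired

        found = self.lookup(username)
        if found is None:
            # Mimic normal failure behaviour for nonexistent usernames:
            # exactly one dummy verification, identical failure shape.
            self._verify(password, self._dummy_hash)
            return self._record_failure(username, now)

        user_id, stored_hash, password_set_at = found
        if not self._verify(password, stored_hash):
            return self._record_failure(username, now)

        if (
            self.config.max_password_age is not None
            and password_set_at is not None
            and now - to_utc(password_set_at) > self.config.max_password_age
        ):
            self.audit("login_rejected_expired_password", username)
            return LoginFailure("password expired")

        state.consecutive_failures = 0
        state.locked_until = None
        session = SessionToken(
            session_id=secrets.token_hex(16),
            token=secrets.token_urlsafe(32),  # fresh at every login
            user_id=user_id,
            created_at=now,
            last_activity=now,
            client_ip=client_ip,
        )
        self.sessions[session.session_id] = session
        self.audit("login", username)
        return session

    def validate_session(
        self, session_id: str, token: str, client_ip: str, now: datetime
    ) -> Optional[int]:
        """Return the user_id for a live session, else None.

        Expired, IP-mismatched and unknown sessions are distinct internally
        but indistinguishable to the caller.  Acceptance refreshes the
        inactivity clock.
        """
        now = to_utc(now)
        session = self.sessions.get(session_id)
        if session is None:
            return None
        if not hmac.compare_digest(session.token, token):
            return None
        if session.client_ip != client_ip:
            return None  # sessions cannot move between client IPs
        if now - session.last_activity > self.config.inactivity_limit:
            del self.sessions[session_id]
            return None
        session.last_activity = now
        return session.user_id

    def logout(self, session_id: str) -> None:
        self.sessions.pop(session_id, None)


# ------------------------------------------- brute-force key-search figure

JULIAN_YEAR_SECONDS = 365.25 * 86_400


def brute_force_mean_cycles(n_bits: int) -> Fraction:
    """Mean cycles to find an n-bit key by exhaustive search: 0.5*2^n + 0.5.

    Exact rational arithmetic; the mean is half-integral.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    return Fraction(2**n_bits + 1, 2)


def brute_force_mean_time(
    n_bits: int,
    attack_hz: float,
    year_seconds: float = JULIAN_YEAR_SECONDS,
) -> float:
    """Mean years to brute-force an n-bit key at the given attack rate.

    At 256 bits and 10 GHz this is ~1.8e59 years — the scale argument for
    trusting AES-256 at rest.
    """
    if attack_hz <= 0 or year_seconds <= 0:
        raise ValueError("attack_hz and year_seconds must be positive")
    cycles = brute_force_mean_cycles(n_bits)
    return float(cycles / (Fraction(attack_hz) * Fraction(year_seconds)))
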
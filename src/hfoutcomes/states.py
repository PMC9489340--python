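"""Shared five-state space: NYHA functional classes I-IV plus the absorbing
composite cardiovascular event (CVE) state."""

from __future__ import annotations

STATES: tuple[str, ...] = ("I", "II", "III", "IV", "CVE")
N_STATES = len(STATES)
CVE = "CVE"
CVE_INDEX = STATES.index(CVE)
NYHA_STATES: tuple[str, ...] = STATES[:CVE_INDEX]

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
# followup.csv encodes NYHA as integers 1-4 and the event as the literal "CVE"
_CSV_CODES = {"1": "I", "2": "II", "3": "III", "4": "IV", "CVE": "CVE"}


def state_index(state: str) -> int:
    """Index of a state label in the canonical ordering."""
    try:
        return _STATE_INDEX[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}") from None


def parse_state(token: str) -> str:
    """Decode a followup.csv state token (1-4 or CVE) to a state label."""
    tok = str(token).strip()
    try:
        return _CSV_CODES[tok]
    except KeyError:
        raise ValueError(
            f"invalid state code {token!r}; expected 1, 2, 3, 4 or CVE"
        ) from None


def encode_state(state: str) -> str:
    """Encode a state label to its followup.csv token."""
    i = state_index(state)
    return "CVE" if state == CVE else str(i + 1)


def parse_nyha(token: int | str) -> str:
    """Decode a NYHA integer code 1-4 to a class label."""
    tok = str(token).strip()
    if tok not in {"1", "2", "3", "4"}:
        raise ValueError(f"NYHA class must be 1-4, got {token!r}")
    return STATES[int(tok) - 1]
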
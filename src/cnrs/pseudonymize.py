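"""Key management for deidentified linkage (the honest-broker component).

The key manager is the only component that ever sees both the raw patient /
pathology identifiers and the pseudonyms that replace them. It issues

* one *alternative ID* per (patient, pathology) pair — the pseudonymous
  report accession, and
* one *patient alternative key* per patient — the linkage key that joins a
  patient's reports and clinical records inside the research warehouse,

and it can strip raw identifier columns from staged tables before they are
loaded downstream (:meth:`KeyManager.scrub_and_link`). Reversal
(:meth:`KeyManager.resolve`) requires the keystore credential.

The unlinkability contract is structural, not cryptographic: pseudonyms are
random tokens sharing no substring of length >= 4 with the identifiers they
replace, and the at-rest keystore is obfuscated with a passphrase-derived
keystream. Stronger guarantees (k-anonymity, formal encryption claims) are
out of scope.
"""

from __future__ import annotations

import base64
import datetime as _dt
import hashlib
import hmac
import json
import os
import random
import stat
from pathlib import Path

import pandas as pd

from .errors import AuthorizationError, CnrsError, LeakError

ALT_ID_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ234567"  # base-32
ALT_ID_PREFIX = "NCC-"
PATIENT_KEY_PREFIX = "NCP-"
_BODY_LEN = 10
_MIN_SHARED = 4  # forbidden shared-substring length with raw IDs


def _checksum(body: str) -> str:
    total = sum(ALT_ID_ALPHABET.index(c) * (i + 1) for i, c in enumerate(body))
    return ALT_ID_ALPHABET[total % len(ALT_ID_ALPHABET)]


def shares_substring(a: str, b: str, k: int = _MIN_SHARED) -> bool:
    """True if ``a`` and ``b`` share any common substring of length ``k``."""
    if len(a) < k or len(b) < k:
        return False
    grams = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in grams for i in range(len(b) - k + 1))


def validate_alt_id(alt_id: str, prefix: str = ALT_ID_PREFIX) -> bool:
    if not alt_id.startswith(prefix):
        return False
    body = alt_id[len(prefix) :]
    if len(body) != _BODY_LEN + 1 or any(c not in ALT_ID_ALPHABET for c in body):
        return False
    return _checksum(body[:-1]) == body[-1]


class KeyMapEntry:
    """One keystore row: (patient_no, pathology_no) -> alt_id."""

    __slots__ = ("patient_no", "pathology_no", "alt_id", "created_at")

    def __init__(self, patient_no: str, pathology_no: str, alt_id: str, created_at: str):
        self.patient_no = patient_no
        self.pathology_no = pathology_no
        self.alt_id = alt_id
        self.created_at = created_at

    def as_dict(self) -> dict[str, str]:
        return {
            "patient_no": self.patient_no,
            "pathology_no": self.pathology_no,
            "alt_id": self.alt_id,
            "created_at": self.created_at,
        }


class KeyManager:
    """Issues and resolves pseudonymous identifiers.

    Parameters
    ----------
    credential:
        Passphrase protecting :meth:`resolve` and at-rest persistence.
    seed:
        Optional integer seed for reproducible pseudonym streams (test
        fixtures); by default the stream is drawn from OS entropy.
    """

    RAW_ID_COLUMNS = ("patient_no", "pathology_no")

    def __init__(self, credential: str | None = None, seed: int | None = None):
        self._rng = random.Random(seed) if seed is not None else random.SystemRandom()
        self._credential_hash = self._hash(credential) if credential else None
        self._entries: dict[tuple[str, str], KeyMapEntry] = {}
        self._by_alt: dict[str, tuple[str, str]] = {}
        self._patient_keys: dict[str, str] = {}
        self._issued: set[str] = set()

    @staticmethod
    def _hash(credential: str) -> str:
        return hashlib.sha256(("cnrs-keystore:" + credential).encode()).hexdigest()

    # -- pseudonym issuance -------------------------------------------------

    def _new_token(self, prefix: str, avoid: tuple[str, ...]) -> str:
        while True:
            body = "".join(self._rng.choice(ALT_ID_ALPHABET) for _ in range(_BODY_LEN))
            token = prefix + body + _checksum(body)
            if token in self._issued:
                continue
            if any(shares_substring(token, raw) for raw in avoid):
                continue
            self._issued.add(token)
            return token

    def register(self, patient_no: str, pathology_no: str) -> str:
        """Issue (or return the existing) alternative ID for a report.

        Idempotent per (patient, pathology) pair; injective across pairs. A
        second pathology accession for the same patient receives a distinct
        alternative ID — cross-report linkage goes through the per-patient
        key instead.
        """
        if not patient_no or not pathology_no:
            raise CnrsError("patient_no and pathology_no must be nonempty")
        pair = (patient_no, pathology_no)
        if pair in self._entries:
            return self._entries[pair].alt_id
        alt_id = self._new_token(ALT_ID_PREFIX, (patient_no, pathology_no))
        self._entries[pair] = KeyMapEntry(
            patient_no, pathology_no, alt_id, _dt.datetime.now().isoformat(timespec="seconds")
        )
        self._by_alt[alt_id] = pair
        self.patient_key(patient_no)  # ensure the patient-level key exists
        return alt_id

    def patient_key(self, patient_no: str) -> str:
        """The per-patient alternative key (stable across that patient's reports)."""
        if not patient_no:
            raise CnrsError("patient_no must be nonempty")
        if patient_no not in self._patient_keys:
            self._patient_keys[patient_no] = self._new_token(
                PATIENT_KEY_PREFIX, (patient_no,)
            )
        return self._patient_keys[patient_no]

    # -- controlled reversal ------------------------------------------------

    def _authorize(self, credential: str | None) -> None:
        if self._credential_hash is None:
            raise AuthorizationError(
                "keystore has no credential configured; resolution is disabled"
            )
        if credential is None or self._hash(credential) != self._credential_hash:
            raise AuthorizationError("invalid or missing keystore credential")

    def resolve(self, alt_id: str, credential: str | None = None) -> tuple[str, str]:
        """Map an alternative ID back to (patient_no, pathology_no).

        Available only with the keystore credential.
        """
        self._authorize(credential)
        if alt_id not in self._by_alt:
            raise CnrsError(f"alternative ID {alt_id!r} is not registered")
        return self._by_alt[alt_id]

    def export_audit(self) -> pd.DataFrame:
        """Deidentified issuance audit: alt IDs and timestamps, no raw IDs."""
        return pd.DataFrame(
            [{"alt_id": e.alt_id, "created_at": e.created_at} for e in self._entries.values()]
        )

    # -- scrubbing staged tables --------------------------------------------

    def scrub_and_link(self, tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
        """Replace raw ID columns with alternative keys across staged tables.

        ``patient_no`` columns become ``alt_patient_key``; ``pathology_no``
        columns become ``alt_id``. Every raw ID encountered must already be
        registered; after substitution the entire output is scanned for any
        registered raw ID as a substring and the batch is refused on a hit.
        Row counts are preserved.
        """
        known_patients = set(self._patient_keys)
        known_paths = {p for (_, p) in self._entries}
        pair_alt = {pair: e.alt_id for pair, e in self._entries.items()}

        out: dict[str, pd.DataFrame] = {}
        offenders: list[str] = []
        for name, frame in tables.items():
            frame = frame.copy()
            if "patient_no" in frame.columns:
                unknown = sorted(set(frame["patient_no"].astype(str)) - known_patients)
                if unknown:
                    offenders.extend(f"{name}.patient_no={u}" for u in unknown)
                    continue
            if "pathology_no" in frame.columns:
                unknown = sorted(set(frame["pathology_no"].astype(str)) - known_paths)
                if unknown:
                    offenders.extend(f"{name}.pathology_no={u}" for u in unknown)
                    continue
            if "patient_no" in frame.columns and "pathology_no" in frame.columns:
                frame["alt_id"] = [
                    pair_alt[(str(a), str(b))]
                    for a, b in zip(frame["patient_no"], frame["pathology_no"])
                ]
            if "patient_no" in frame.columns:
                frame["alt_patient_key"] = frame["patient_no"].astype(str).map(
                    self._patient_keys
                )
                frame = frame.drop(columns=["patient_no"])
            if "pathology_no" in frame.columns:
                if "alt_id" not in frame.columns:
                    raise CnrsError(
                        f"table {name!r} has pathology_no without patient_no; "
                        "cannot resolve the (patient, pathology) pair"
                    )
                frame = frame.drop(columns=["pathology_no"])
            out[name] = frame

        if offenders:
            raise CnrsError(
                f"{len(offenders)} unregistered raw identifier(s): "
                + ", ".join(offenders[:10])
            )

        raw_ids = sorted(known_patients | known_paths)
        for name, frame in out.items():
            leaks = scan_frame_for_ids(frame, raw_ids)
            if leaks:
                raise LeakError(f"raw identifiers leaked in table {name!r}: {leaks[:5]}")
        return out

    # -- persistence ---------------------------------------------------------

    def _payload(self) -> dict:
        return {
            "entries": [e.as_dict() for e in self._entries.values()],
            "patient_keys": self._patient_keys,
        }

    def save(self, path: str | Path, credential: str) -> None:
        """Persist the keystore, obfuscated with a passphrase-derived keystream."""
        if self._credential_hash is not None and self._hash(credential) != self._credential_hash:
            raise AuthorizationError("credential does not match this keystore")
        salt = os.urandom(16)
        plain = json.dumps(self._payload()).encode()
        blob = _keystream_xor(plain, credential, salt)
        doc = {
            "format": "cnrs-keystore-v1",
            "salt": base64.b64encode(salt).decode(),
            "credential_hash": self._hash(credential),
            "data": base64.b64encode(blob).decode(),
        }
        p = Path(path)
        p.write_text(json.dumps(doc), encoding="utf-8")
        p.chmod(stat.S_IRUSR | stat.S_IWUSR)  # 0600

    @classmethod
    def load(cls, path: str | Path, credential: str, seed: int | None = None) -> "KeyManager":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format") != "cnrs-keystore-v1":
            raise CnrsError(f"{path} is not a keystore file")
        if cls._hash(credential) != doc["credential_hash"]:
            raise AuthorizationError("invalid keystore credential")
        salt = base64.b64decode(doc["salt"])
        plain = _keystream_xor(base64.b64decode(doc["data"]), credential, salt)
        payload = json.loads(plain.decode())
        km = cls(credential=credential, seed=seed)
        for row in payload["entries"]:
            entry = KeyMapEntry(
                row["patient_no"], row["pathology_no"], row["alt_id"], row["created_at"]
            )
            km._entries[(entry.patient_no, entry.pathology_no)] = entry
            km._by_alt[entry.alt_id] = (entry.patient_no, entry.pathology_no)
            km._issued.add(entry.alt_id)
        km._patient_keys = dict(payload["patient_keys"])
        km._issued.update(km._patient_keys.values())
        return km


def _keystream_xor(data: bytes, passphrase: str, salt: bytes) -> bytes:
    key = hashlib.pbkdf2_hmac("sha256", passphrase.encode(), salt, 50_000)
    out = bytearray()
    counter = 0
    while len(out) < len(data):
        block = hmac.new(key, salt + counter.to_bytes(8, "big"), hashlib.sha256).digest()
        out.extend(block)
        counter += 1
    return bytes(a ^ b for a, b in zip(data, out))


def scan_frame_for_ids(frame: pd.DataFrame, raw_ids: list[str]) -> list[str]:
    """Identifiers from ``raw_ids`` occurring as substrings in any cell or column name."""
    blob = "\x1f".join(map(str, frame.columns))
    if not frame.empty:
        blob += "\x1f" + "\x1f".join(frame.astype(str).to_numpy().ravel())
    return [i for i in raw_ids if i and i in blob]
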
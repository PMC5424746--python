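"""Gateway-to-node model-transfer protocol.

After training on the personal gateway (a smartphone in the deployed
system), the packed SVM model is pushed to the wearable node over a
stop-and-wait link: the gateway sends one packet, waits for the node's
acknowledgment, and only then sends the next.  Three packet types are
used, in fixed order:

* ``CONFIG`` — SVM type, gamma, number of classes, number of features;
* ``MODEL_PARAMS`` — the rho offsets, the total SV count and the per-class
  SV counts;
* ``SV`` — one packet per support vector, carrying the vector and its
  pre-computed coefficients.

Every packet carries a one-byte two's-complement checksum over header and
payload (any single corrupted byte changes the modular sum, so all
single-byte errors are detected); a checksum failure or an out-of-order
packet is answered with a NAK and the gateway retransmits, up to a retry
limit.  Field encodings are identical to the flash-image serialization, so
a completed transfer assembles a model bit-identical to the sent one.

Both endpoints live in-process here; the lossy channel between them is
injectable for fault-injection testing.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field

import numpy as np

from .gestures import Gesture
from .svm import SvmModel

DEFAULT_RETRY_LIMIT = 5


class PacketType(enum.IntEnum):
    CONFIG = 1
    MODEL_PARAMS = 2
    SV = 3


#: Single-byte mode-switch commands (streaming / update / classification).
MODE_COMMANDS = {"SM": 0x53, "UM": 0x55, "CM": 0x43}

_CONFIG_STRUCT = struct.Struct("<BfHH")   # svm type, gamma, NCl, NF
_SV_TYPE_RBF_OVO = 1


def checksum(data: bytes) -> int:
    """One-byte two's-complement sum: sum(data + [checksum]) % 256 == 0."""
    return (-sum(data)) & 0xFF


@dataclass(frozen=True)
class Packet:
    ptype: PacketType
    seq: int
    payload: bytes
    checksum: int

    @classmethod
    def make(cls, ptype: PacketType, seq: int, payload: bytes) -> "Packet":
        return cls(ptype, seq, payload, checksum(cls._summed(ptype, seq, payload)))

    @staticmethod
    def _summed(ptype: int, seq: int, payload: bytes) -> bytes:
        return bytes([int(ptype)]) + struct.pack("<H", seq) + payload

    def verify(self) -> bool:
        body = self._summed(self.ptype, self.seq, self.payload)
        return (sum(body) + self.checksum) & 0xFF == 0

    def to_bytes(self) -> bytes:
        return self._summed(self.ptype, self.seq, self.payload) + bytes([self.checksum])

    @classmethod
    def from_bytes(cls, raw: bytes) -> "Packet":
        if len(raw) < 4:
            raise ValueError("packet shorter than header+checksum")
        ptype = raw[0]
        (seq,) = struct.unpack_from("<H", raw, 1)
        return cls(ptype, seq, raw[3:-1], raw[-1])


def encode_model(model: SvmModel) -> list:
    """Split a packed model into its 2 + NS transfer packets."""
    packets = [
        Packet.make(PacketType.CONFIG, 0, _CONFIG_STRUCT.pack(
            _SV_TYPE_RBF_OVO, np.float32(model.gamma),
            model.n_classes, model.n_features)),
    ]
    params = struct.pack("<I", model.n_sv)
    params += np.asarray(model.rho, "<f4").tobytes()
    for lab, cnt in zip(model.class_labels, model.sv_counts):
        params += struct.pack("<HH", int(lab), int(cnt))
    packets.append(Packet.make(PacketType.MODEL_PARAMS, 1, params))
    for i in range(model.n_sv):
        payload = (np.ascontiguousarray(model.support_vectors[i], "<f4").tobytes()
                   + np.ascontiguousarray(model.coefficients[i], "<f4").tobytes())
        packets.append(Packet.make(PacketType.SV, 2 + i, payload))
    return packets


class SessionState(enum.Enum):
    AWAIT_CONFIG = "AWAIT_CONFIG"
    AWAIT_PARAMS = "AWAIT_PARAMS"
    AWAIT_SVS = "AWAIT_SVS"
    DONE = "DONE"
    FAILED = "FAILED"


@dataclass
class TransferSession:
    """Node-side assembly state of one model transfer."""

    state: SessionState = SessionState.AWAIT_CONFIG
    gamma: float = 0.0
    n_classes: int = 0
    n_features: int = 0
    n_sv: int = 0
    class_labels: list = field(default_factory=list)
    sv_counts: list = field(default_factory=list)
    rho: np.ndarray | None = None
    sv_rows: list = field(default_factory=list)
    coef_rows: list = field(default_factory=list)
    assembled: SvmModel | None = None

    @property
    def received_sv_count(self) -> int:
        return len(self.sv_rows)


ACK, NAK = "ACK", "NAK"

_EXPECTED = {
    SessionState.AWAIT_CONFIG: PacketType.CONFIG,
    SessionState.AWAIT_PARAMS: PacketType.MODEL_PARAMS,
    SessionState.AWAIT_SVS: PacketType.SV,
}


def node_receive(session: TransferSession, packet: Packet):
    """Process one packet on the node; returns ``(session, (ACK|NAK, reason))``.

    A checksum failure or an out-of-order packet type leaves the session
    unchanged and answers NAK; the gateway then retransmits.  The final SV
    packet assembles and validates the model and moves the session to DONE.
    """
    if session.state is SessionState.FAILED:
        raise RuntimeError("session already failed")
    if session.state is SessionState.DONE:
        return session, (NAK, "transfer already complete")
    if not packet.verify():
        return session, (NAK, "checksum mismatch")
    expected = _EXPECTED[session.state]
    if packet.ptype != expected:
        return session, (NAK, f"expected {expected.name} packet, "
                              f"got type {int(packet.ptype)}")
    try:
        if packet.ptype == PacketType.CONFIG:
            svtype, gamma, ncl, nf = _CONFIG_STRUCT.unpack(packet.payload)
            if svtype != _SV_TYPE_RBF_OVO:
                return session, (NAK, "unsupported SVM type")
            session.gamma, session.n_classes, session.n_features = gamma, ncl, nf
            session.state = SessionState.AWAIT_PARAMS
        elif packet.ptype == PacketType.MODEL_PARAMS:
            npairs = session.n_classes * (session.n_classes - 1) // 2
            (ns,) = struct.unpack_from("<I", packet.payload)
            off = 4
            session.rho = np.frombuffer(packet.payload, "<f4", npairs, off).copy()
            off += 4 * npairs
            labels, counts = [], []
            for _ in range(session.n_classes):
                lab, cnt = struct.unpack_from("<HH", packet.payload, off)
                labels.append(Gesture(lab))
                counts.append(cnt)
                off += 4
            if sum(counts) != ns:
                return session, (NAK, "per-class SV counts do not sum to NS")
            session.n_sv = ns
            session.class_labels, session.sv_counts = labels, counts
            session.state = SessionState.AWAIT_SVS
        else:  # SV packet
            nf, ncl = session.n_features, session.n_classes
            expect_len = 4 * nf + 4 * (ncl - 1)
            if len(packet.payload) != expect_len:
                return session, (NAK, "SV packet payload length mismatch")
            if packet.seq != 2 + session.received_sv_count:
                if packet.seq == 1 + session.received_sv_count:
                    return session, (ACK, "duplicate SV packet ignored")
                return session, (NAK, "unexpected SV sequence number")
            session.sv_rows.append(np.frombuffer(packet.payload, "<f4", nf).copy())
            session.coef_rows.append(
                np.frombuffer(packet.payload, "<f4", ncl - 1, 4 * nf).copy())
            if session.received_sv_count == session.n_sv:
                session.assembled = SvmModel(
                    session.n_features, session.n_classes, session.gamma,
                    session.class_labels, np.asarray(session.sv_counts),
                    np.vstack(session.sv_rows), np.vstack(session.coef_rows),
                    session.rho,
                )
                session.state = SessionState.DONE
    except (struct.error, ValueError) as exc:
        return session, (NAK, f"malformed payload: {exc}")
    return session, (ACK, "")


class LossyChannel:
    """Byte-corrupting channel model with a configurable error rate.

    With probability ``corrupt_prob`` a transiting packet has one random
    byte XOR-ed with a random non-zero value.  ACK/NAK responses are
    modeled as reliable (the deployed protocol defines no ACK-loss
    recovery).  Deterministic given the seed.
    """

    def __init__(self, corrupt_prob: float = 0.0, seed: int = 0):
        if not 0.0 <= corrupt_prob <= 1.0:
            raise ValueError("corrupt_prob must lie in [0, 1]")
        self.corrupt_prob = corrupt_prob
        self.rng = np.random.default_rng(seed)
        self.corrupted = 0

    def transmit(self, packet: Packet) -> Packet:
        if self.corrupt_prob and self.rng.random() < self.corrupt_prob:
            raw = bytearray(packet.to_bytes())
            pos = int(self.rng.integers(len(raw)))
            raw[pos] ^= int(self.rng.integers(1, 256))
            self.corrupted += 1
            return Packet.from_bytes(bytes(raw))
        return packet


@dataclass
class TransferReport:
    outcome: str                 # DONE | FAILED
    packets: int                 # distinct packets in the model
    transmissions: int           # total sends including retries
    retries: int
    acks: int
    naks: int
    failed_packet: int | None = None

    @property
    def ok(self) -> bool:
        return self.outcome == "DONE"


def gateway_send(model: SvmModel, channel: LossyChannel | None = None,
                 retry_limit: int = DEFAULT_RETRY_LIMIT,
                 session: TransferSession | None = None,
                 packet_log: list | None = None):
    """Push a model through the stop-and-wait protocol.

    Returns ``(report, session)``; on success ``session.assembled`` is the
    reassembled model (field-for-field identical to the input).  Each
    packet is retransmitted on NAK up to ``retry_limit`` times before the
    transfer is abandoned.
    """
    channel = channel or LossyChannel()
    session = session or TransferSession()
    packets = encode_model(model)
    transmissions = retries = acks = naks = 0
    for pkt in packets:
        for attempt in range(retry_limit + 1):
            transmissions += 1
            if attempt:
                retries += 1
            delivered = channel.transmit(pkt)
            if packet_log is not None:
                packet_log.append(delivered.to_bytes().hex())
            session, (resp, _reason) = node_receive(session, delivered)
            if resp == ACK:
                acks += 1
                break
            naks += 1
        else:
            session.state = SessionState.FAILED
            return TransferReport("FAILED", len(packets), transmissions,
                                  retries, acks, naks,
                                  failed_packet=pkt.seq), session
    return TransferReport("DONE", len(packets), transmissions,
                          retries, acks, naks), session
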
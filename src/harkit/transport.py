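"""Thin loopback transport demo for streamed sensor rows.

The real-time deployment streams sensor rows from a phone to a classifier
over TCP as newline-delimited CSV (``t,ax,ay,az,gx,gy,gz``) at the
recording rate. This module provides just enough of that protocol to demo
the streaming loop locally: an encoder/decoder for row lines and a pair of
helpers that push a stream through any connected socket. It is a demo
harness, not a production transport.
"""

from __future__ import annotations

import socket
from typing import Iterator, List

import numpy as np

from .sensor_io import ActivityStream, CSV_DECIMALS, SensorReading


def encode_reading(reading: SensorReading) -> bytes:
    """One CSV line (no header), newline-terminated."""
    return (",".join(f"{v:.{CSV_DECIMALS}f}" for v in reading) + "\n").encode()


def decode_reading(line: bytes) -> SensorReading:
    parts = line.decode().strip().split(",")
    if len(parts) != 7:
        raise ValueError(f"expected 7 comma-separated values, got {len(parts)}")
    return SensorReading(*map(float, parts))


def send_stream(sock: socket.socket, stream: ActivityStream) -> int:
    """Write every reading to the socket; returns the row count."""
    for reading in stream:
        sock.sendall(encode_reading(reading))
    return len(stream)


def receive_readings(sock: socket.socket, n_rows: int) -> List[SensorReading]:
    """Read exactly ``n_rows`` newline-delimited rows from the socket."""
    buf = b""
    rows: List[SensorReading] = []
    while len(rows) < n_rows:
        chunk = sock.recv(4096)
        if not chunk:
            raise ConnectionError(
                f"peer closed after {len(rows)} of {n_rows} rows")
        buf += chunk
        while b"\n" in buf and len(rows) < n_rows:
            line, buf = buf.split(b"\n", 1)
            rows.append(decode_reading(line))
    return rows
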
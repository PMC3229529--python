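"""Compression ratio and transmission-time accounting.

The evaluation question behind the codec is how long a compressed alignment
file takes to move over a fixed link. The reference link is a T1 line
(1.544 Mbps, i.e. 0.193 MB/s), and sizes quoted in GB convert to MB with a
factor of 1024. Offline transfers count the transmission time of the final
file alone; online transfers add compression and decompression time on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SamzipError

#: T1 line rate in megabytes per second (1.544 Mbps / 8)
T1_BANDWIDTH_MBPS = 0.193

GB_TO_MB = 1024.0
_BYTES_PER_GB = 1024.0**3


@dataclass(frozen=True)
class TransmissionModel:
    """A constant-rate link; bandwidth in MB/s."""

    bandwidth_mbps: float = T1_BANDWIDTH_MBPS

    def __post_init__(self) -> None:
        if self.bandwidth_mbps <= 0:
            raise SamzipError("bandwidth must be positive")


def transmission_seconds(size_gb: float, bandwidth_mbps: float = T1_BANDWIDTH_MBPS) -> float:
    """Seconds to move ``size_gb`` gigabytes at ``bandwidth_mbps`` MB/s.

    ``size_gb`` converts to megabytes with the 1024 factor, so 3.5 GB over a
    T1 line is 3584/0.193 ≈ 18569.95 s. Linear in size, inverse in rate.
    """
    if size_gb < 0:
        raise SamzipError("size must be non-negative")
    if bandwidth_mbps <= 0:
        raise SamzipError("bandwidth must be positive")
    return size_gb * GB_TO_MB / bandwidth_mbps


def transmission_minutes(size_gb: float, bandwidth_mbps: float = T1_BANDWIDTH_MBPS) -> float:
    return transmission_seconds(size_gb, bandwidth_mbps) / 60.0


@dataclass
class CompressionReport:
    """Sizes and phase timings for one compress/decompress cycle."""

    original_bytes: int
    encoded_bytes: int
    final_bytes: int
    per_field_bytes: dict[str, int] = field(default_factory=dict)
    encode_seconds: float | None = None
    post_seconds: float | None = None
    decode_seconds: float | None = None

    def __post_init__(self) -> None:
        if min(self.original_bytes, self.encoded_bytes, self.final_bytes) < 0:
            raise SamzipError("sizes must be non-negative")

    @property
    def ratio(self) -> float:
        """Compression ratio, original/final."""
        return self.original_bytes / self.final_bytes if self.final_bytes else float("inf")

    @property
    def final_gb(self) -> float:
        return self.final_bytes / _BYTES_PER_GB


def total_online_time(report: CompressionReport, model: TransmissionModel | None = None) -> float:
    """Online-scenario total: compression + transmission of the final file + decompression."""
    model = model or TransmissionModel()
    timings = (report.encode_seconds, report.post_seconds, report.decode_seconds)
    if any(t is None for t in timings):
        raise SamzipError("report lacks phase timings; run measure_roundtrip first")
    return sum(timings) + transmission_seconds(report.final_gb, model.bandwidth_mbps)
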
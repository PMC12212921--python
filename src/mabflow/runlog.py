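"""Self-documenting run records.

Every pipeline invocation that writes output also writes exactly one run
log: the step name, parameters, input and output files, user, start/end
timestamps and progress messages.  Logs are written once (append-only
archive, never overwritten) as human-readable text plus a machine-readable
JSON sidecar.
"""

from __future__ import annotations

import getpass
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path


@dataclass
class RunLog:
    step: str
    parameters: dict = field(default_factory=dict)
    input_files: list[str] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)
    user: str = ""
    started_at: str = ""
    finished_at: str = ""
    messages: list[str] = field(default_factory=list)
    _written: bool = field(default=False, repr=False)

    @classmethod
    def start(cls, step: str, parameters: dict | None = None) -> "RunLog":
        try:
            user = getpass.getuser()
        except Exception:
            user = "unknown"
        return cls(
            step=step,
            parameters=dict(parameters or {}),
            user=user,
            started_at=datetime.now(timezone.utc).isoformat(),
        )

    def log(self, message: str) -> None:
        self.messages.append(message)

    def add_input(self, path) -> None:
        self.input_files.append(str(path))

    def add_output(self, path) -> None:
        self.output_files.append(str(path))

    def write(self, directory: str | Path) -> Path:
        """Finalize and persist the log; a RunLog can be written only once."""
        if self._written:
            raise RuntimeError(f"run log for step {self.step!r} was already written")
        self.finished_at = datetime.now(timezone.utc).isoformat()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S")
        base = directory / f"runlog_{self.step}_{stamp}"
        path, counter = base.with_suffix(".txt"), 1
        while path.exists():
            path = directory / f"runlog_{self.step}_{stamp}_{counter}.txt"
            counter += 1
        lines = [
            f"step:      {self.step}",
            f"user:      {self.user}",
            f"started:   {self.started_at}",
            f"finished:  {self.finished_at}",
            "parameters:",
            *(f"  {k} = {v}" for k, v in self.parameters.items()),
            "input files:",
            *(f"  {p}" for p in self.input_files),
            "output files:",
            *(f"  {p}" for p in self.output_files),
            "messages:",
            *(f"  {m}" for m in self.messages),
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        sidecar = path.with_suffix(".json")
        payload = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        sidecar.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        self._written = True
        return path
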
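"""Local executor implementing the job-scheduler contract.

Real deployments hand docking jobs to a cluster queue (Slurm, SGE); the
pipeline only relies on a minimal submit/collect contract, so any queueing
system can be adapted.  The shipped implementation runs jobs in a local
thread pool with bounded retries.  Results are returned in submission
order regardless of completion order, which — together with per-candidate
seeds derived from the master seed — makes runs invariant to the worker
count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor

__all__ = ["LocalExecutor", "SlurmExecutorStub", "SgeExecutorStub"]


class LocalExecutor:
    """Thread-pool executor with retries; results in submission order."""

    def __init__(self, workers: int = 1, retries: int = 0):
        if workers < 1:
            raise ValueError("workers must be >= 1")
        self.workers = workers
        self.retries = retries

    def map(self, fn, items):
        items = list(items)
        if self.workers == 1:
            return [self._call(fn, item) for item in items]
        with ThreadPoolExecutor(max_workers=self.workers) as pool:
            futures = [pool.submit(self._call, fn, item) for item in items]
            return [f.result() for f in futures]

    def _call(self, fn, item):
        attempts = self.retries + 1
        for attempt in range(attempts):
            try:
                return fn(item)
            except Exception:
                if attempt == attempts - 1:
                    raise
        raise AssertionError("unreachable")


class SlurmExecutorStub:
    """Documented adapter surface for a Slurm queue (sbatch/squeue/sacct); untested stub."""

    def map(self, fn, items):
        raise NotImplementedError("Slurm adapter is a documented interface stub")


class SgeExecutorStub:
    """Documented adapter surface for an SGE queue (qsub/qstat); untested stub."""

    def map(self, fn, items):
        raise NotImplementedError("SGE adapter is a documented interface stub")
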
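feature,group
LineCount0Strict,congestion
AheadCount,congestion
StartTime4,time
DelayedInLine,congestion
InProgressSize,congestion
NumCompletedToday,congestion
NumScheduledNextSlot,congestion
LineCount0,congestion
NumScheduledNext60,congestion
AvgWaitForDay,congestion
SumHowEarlyWaiting,congestion
AfterSlot,time
SumWaits,congestion
ScheduledFlowCount30,congestion
SumDelayInProgress,congestion
BeforeSlot,time
IsFirst,congestion
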
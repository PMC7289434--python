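feature,group
LineCount0Strict,congestion
AheadCount,congestion
StartTime,time
StartTime2,time
StartTime3,time
StartTime4,time
NumCompletedToday,congestion
DelayedInLine,congestion
AvgWaitLastK3Customers,congestion
Median5,congestion
SumDelayInProgress,congestion
BeforeSlot,time
SumWaits,congestion
DelayCount,congestion
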
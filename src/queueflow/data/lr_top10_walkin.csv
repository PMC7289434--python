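feature,group
LineCount0,congestion
AheadCount,congestion
NoneInLine,congestion
NoneInProgress,congestion
NoneCompleted,congestion
StartTime4,time
InProgressSize,congestion
NumCompletedToday,congestion
NumCompletedInLast30,congestion
AvgWaitLast30,congestion
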
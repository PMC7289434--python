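feature,group
LineCount0,congestion
AheadCount,congestion
StartTime,time
StartTime2,time
StartTime3,time
StartTime4,time
SumTimeToCompleteInProgress,congestion
SumDelayInProgress,congestion
NumCustomersInLast30,congestion
SumWaits,congestion
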